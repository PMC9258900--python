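"""Agreement metrics between original and extracted models.

Energy agreement is the root-mean-squared energy error normalized by the
range of the original energies on the evaluation set:

    NRMSE = sqrt( mean_m (E^M(s_m) - E^pw(s_m))^2 ) / (max_m E^M - min_m E^M).

Mutational-effect performance is the Spearman rank correlation between
-E(mutant) and the experimental fitness (lower energy = higher predicted
fitness, so a good model scores positive rho).  Structural couplings are
compared by the standard direct-coupling-analysis recipe: zero-sum gauge,
per-pair Frobenius norm excluding the gap symbol, average product correction
(APC), minimum sequence separation, precision among the top-ranked pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import MutationalDataset, SplitResult, _min_hamming_matrix
from .energy import EnergyModel, PairwiseModel, pair_list, to_zero_sum_gauge


def nrmse(E_orig: np.ndarray, E_ext: np.ndarray) -> float:
    """Root-mean-squared error normalized by the range of ``E_orig``."""
    E_orig = np.asarray(E_orig, dtype=float)
    E_ext = np.asarray(E_ext, dtype=float)
    if E_orig.shape != E_ext.shape or E_orig.ndim != 1 or len(E_orig) == 0:
        raise ValueError("energy vectors must be equal-length, nonzero 1-D arrays")
    rng = E_orig.max() - E_orig.min()
    if rng <= 0:
        raise ValueError("original energies have zero range; NRMSE undefined")
    return float(np.sqrt(np.mean((E_orig - E_ext) ** 2)) / rng)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (Pearson on mean ranks; ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def mutational_spearman(model: EnergyModel, data: MutationalDataset, **energy_kwargs) -> float:
    """Rank agreement between -E(mutant) and experimental fitness."""
    if not data.records:
        raise ValueError("mutational dataset has no records")
    mutants = data.mutant_codes()
    E = model.energy(mutants, **energy_kwargs)
    return spearman(-E, data.fitness)


@dataclass
class ContactMap:
    """Unordered position pairs labeled as structural contacts."""

    pairs: set[tuple[int, int]]
    N: int
    min_separation: int = 5

    def __post_init__(self) -> None:
        norm = set()
        for i, j in self.pairs:
            if i == j or not (0 <= i < self.N and 0 <= j < self.N):
                raise ValueError(f"invalid contact pair ({i}, {j})")
            norm.add((min(i, j), max(i, j)))
        self.pairs = norm

    @classmethod
    def read(cls, path, N: int, min_separation: int = 5) -> "ContactMap":
        """Read a 3-column text file ``i j label`` (header may declare
        ``# base=0`` or ``# base=1``; default 0-based)."""
        base = 0
        pairs = set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "base=1" in line.replace(" ", ""):
                        base = 1
                    continue
                i, j, label = line.split()[:3]
                if int(float(label)) == 1:
                    pairs.add((int(i) - base, int(j) - base))
        return cls(pairs=pairs, N=N, min_separation=min_separation)


def contact_scores(
    model: PairwiseModel, exclude_last_symbol: bool | None = None, apc: bool = True
) -> np.ndarray:
    """APC-corrected Frobenius coupling scores, symmetric (N, N), diagonal 0.

    The model is moved to the zero-sum gauge first; each pair score is the
    Frobenius norm of its coupling block restricted to the amino-acid symbols
    (the gap — the alphabet's trailing '-' — is excluded by default when
    present).  The average product correction subtracts
    row_mean * col_mean / grand_mean; an all-zero score matrix is returned
    unchanged.
    """
    m = to_zero_sum_gauge(model)
    if exclude_last_symbol is None:
        exclude_last_symbol = m.alphabet.endswith("-")
    k = m.q - 1 if exclude_last_symbol else m.q
    N = m.N
    F = np.zeros((N, N))
    for p, (i, j) in enumerate(pair_list(N)):
        F[i, j] = F[j, i] = np.sqrt(np.sum(m.J[p][:k, :k] ** 2))
    if not apc:
        return F
    grand = F.sum() / (N * (N - 1)) if N > 1 else 0.0
    if grand == 0:
        return F
    row = F.sum(axis=1) / (N - 1)
    corrected = F - np.outer(row, row) / grand
    np.fill_diagonal(corrected, 0.0)
    return corrected


def ppv_curve(
    scores: np.ndarray,
    truth: ContactMap,
    top_n: int = 200,
    min_separation: int | None = None,
) -> np.ndarray:
    """Precision among the top-k ranked pairs, for k = 1..top_n.

    Pairs with |i - j| >= min_separation are ranked by score descending, ties
    broken lexicographically by (i, j).  If fewer eligible pairs exist than
    ``top_n`` the curve is truncated (with a warning).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    sep = truth.min_separation if min_separation is None else min_separation
    N = scores.shape[0]
    eligible = [(i, j) for i in range(N) for j in range(i + 1, N) if j - i >= sep]
    eligible.sort(key=lambda ij: (-scores[ij[0], ij[1]], ij))
    if len(eligible) < top_n:
        warnings.warn(
            f"only {len(eligible)} eligible pairs; PPV curve truncated", stacklevel=2
        )
    ranked = eligible[:top_n]
    hits = np.cumsum([1.0 if ij in truth.pairs else 0.0 for ij in ranked])
    return hits / np.arange(1, len(ranked) + 1)


def coupling_scatter(
    extracted: PairwiseModel,
    reference: PairwiseModel,
    n_points: int = 5000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Paired zero-sum-gauge coupling values from two models, plus Pearson r.

    A uniformly random subset of min(n_points, total) coupling entries is
    drawn (same entries from both models after gauge fixing).
    """
    if (extracted.N, extracted.q) != (reference.N, reference.q):
        raise ValueError("models must share (N, q)")
    a = to_zero_sum_gauge(extracted).J.ravel()
    b = to_zero_sum_gauge(reference).J.ravel()
    rng = np.random.default_rng(seed)
    k = min(n_points, a.size)
    idx = rng.choice(a.size, size=k, replace=False)
    x, y = a[idx], b[idx]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return x, y, r


@dataclass
class EvaluationReport:
    """NRMSE per stratum per extracted model, Spearman per model, diagnostics.

    ``nrmse`` maps extracted-model label -> {"test_close", "test_distant",
    "mutational"} -> value (None where a stratum is empty).  ``spearman``
    maps model label (original included) -> rho.  ``diagnostics`` holds the
    per-test-sequence distance/energy/error table and binned summaries.
    """

    nrmse: dict = field(default_factory=dict)
    spearman: dict = field(default_factory=dict)
    energies: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    # wall-clock stage timings; informational only, excluded from to_json so
    # reports with identical seeds serialize identically
    timings: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        payload = json.dumps(
            clean(
                {
                    "nrmse": self.nrmse,
                    "spearman": self.spearman,
                    "diagnostics": self.diagnostics,
                    "metadata": self.metadata,
                }
            ),
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def nrmse_table(self) -> pd.DataFrame:
        rows = [
            {"model": label, "stratum": stratum, "nrmse": value}
            for label, strata in self.nrmse.items()
            for stratum, value in strata.items()
        ]
        return pd.DataFrame(rows)


def stratified_energy_report(
    original: EnergyModel,
    extracted_models: dict[str, EnergyModel],
    split: SplitResult,
    mutdata: MutationalDataset | None = None,
    original_energy_seed: int = 0,
) -> EvaluationReport:
    """NRMSE of each extracted model on the three evaluation strata.

    Strata: the 'close' and 'distant' test subsets (by minimum Hamming
    distance to the training set) and, when provided, the mutational-dataset
    sequences.  Also records per-distance diagnostics on the test set: the
    original energies, the per-sequence absolute error of each extracted
    model, and the binned standard deviation of original energies and RMSE
    per unique observed distance.
    """
    report = EvaluationReport(metadata={"split_seed": split.split_seed})
    labels = np.asarray(split.test_labels)
    strata: dict[str, np.ndarray] = {
        "test_close": split.test.codes[labels == "close"],
        "test_distant": split.test.codes[labels == "distant"],
    }
    if mutdata is not None:
        strata["mutational"] = mutdata.mutant_codes()

    orig_kwargs = {"seed": original_energy_seed} if original.energy_is_estimate else {}
    E_orig = {name: original.energy(c, **orig_kwargs) if len(c) else np.empty(0)
              for name, c in strata.items()}
    report.energies["original"] = {k: v for k, v in E_orig.items()}

    for label, model in extracted_models.items():
        report.nrmse[label] = {}
        report.energies[label] = {}
        for name, codes in strata.items():
            # empty or degenerate (zero-energy-range) strata are recorded as
            # missing rather than raising
            if len(codes) == 0 or np.ptp(E_orig[name]) == 0:
                report.nrmse[label][name] = None
                continue
            E_ext = model.energy(codes)
            report.energies[label][name] = E_ext
            report.nrmse[label][name] = nrmse(E_orig[name], E_ext)

    # Fig-6-style distance diagnostics on the full test set
    dists = _min_hamming_matrix(split.test, split.train)
    E_test = original.energy(split.test.codes, **orig_kwargs)
    diag: dict = {"distance": dists, "original_energy": E_test}
    uniq = np.unique(dists)
    diag["bins"] = uniq
    diag["energy_sd_per_bin"] = np.array(
        [E_test[dists == d].std() for d in uniq]
    )
    for label, model in extracted_models.items():
        err = np.abs(E_test - model.energy(split.test.codes))
        diag[f"abs_error:{label}"] = err
        diag[f"rmse_per_bin:{label}"] = np.array(
            [np.sqrt(np.mean(err[dists == d] ** 2)) for d in uniq]
        )
    report.diagnostics = diag

    if mutdata is not None and len(mutdata.records) >= 3:
        report.spearman["original"] = spearman(-E_orig["mutational"], mutdata.fitness)
        for label, model in extracted_models.items():
            report.spearman[label] = mutational_spearman(model, mutdata)
    return report
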