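"""Distillation of pairwise / independent models from arbitrary energy models.

Given an original model with energy E^M(s) and a distribution D over
sequences, extraction minimizes the mean squared energy error

    L(J, h, C) = E_{s ~ D} [ (E^M(s) - E^pw(s))^2 ],

over the parameters of a pairwise model (independent models fix J = 0).
Three routes are provided:

* ``extract_exact`` — the oracle: weighted least squares over a full
  enumeration of sequence space (toy sizes), using the pseudo-inverse so the
  gauge null directions are resolved to the minimum-norm solution.
* ``extract_uniform_closed_form`` — for D = U the minimizer is available in
  closed form from conditional means of E^M under uniform sampling (the
  zero-sum / Möbius expansion truncated at order two); estimated here from a
  finite uniform sample.
* ``extract_sgd`` — the general protocol for D = M (or any explicit sample
  set): prepare n_samples sequences with their original-model energies, then
  run Adam on minibatches resampled with replacement, independently replacing
  each in-batch sample with a fresh uniform sequence with probability 1%
  (its energy computed on the fly), tracking an exponential moving average of
  batch losses (factor 0.9) and stopping once the EMA has not improved for
  1000 steps; parameters start at 0 and the returned parameters are the
  checkpoint at the best EMA.

The choice of D selects a gauge: for D = U the extracted pairwise part is
the zero-sum-gauge pairwise part of E^M, while D = M concentrates fidelity
near the model's own high-probability region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .alignment import EncodedAlignment
from .energy import (
    EnergyModel,
    IndependentModel,
    PairwiseModel,
    enumerate_sequences,
    n_pairs,
    pair_list,
    to_zero_sum_gauge,
)


@dataclass
class ExtractionConfig:
    """Settings for the stochastic extraction protocol.

    Defaults follow the reference protocol: 10^7 prepared samples, batch size
    10000, 1% uniform mixing, EMA factor 0.9, patience 1000 steps, all
    parameters initialized to 0.  ``max_steps`` is a safety cap; ``k_target``
    is the number of importance samples used per target energy when the
    original model only provides estimated energies.
    """

    distribution: str = "M"  # U | M | explicit
    family: str = "pairwise"  # pairwise | independent
    n_samples: int = 10**7
    batch_size: int = 10000
    uniform_mix_prob: float = 0.01
    ema_factor: float = 0.9
    patience_steps: int = 1000
    step_size: float = 1e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)
    max_steps: int = 200_000
    k_target: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.uniform_mix_prob <= 1.0:
            raise ValueError("uniform_mix_prob must be in [0, 1]")
        if not 0.0 <= self.ema_factor < 1.0:
            raise ValueError("ema_factor must be in [0, 1)")
        if min(self.n_samples, self.batch_size, self.patience_steps) < 1:
            raise ValueError("counts must be positive")
        if self.family not in ("pairwise", "independent"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.distribution not in ("U", "M", "explicit"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


@dataclass
class EnergySampleSet:
    """Sequences from a distribution D paired with original-model energies."""

    sequences: EncodedAlignment
    energies: np.ndarray
    source: str = "explicit"  # U | M | explicit
    estimator: dict = field(default_factory=lambda: {"kind": "exact"})

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.energies) != len(self.sequences):
            raise ValueError("one energy per sequence required")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energies must be finite")

    def __len__(self) -> int:
        return len(self.sequences)


def sample_uniform(N: int, q: int, n: int, seed: int = 0) -> EncodedAlignment:
    """n i.i.d. sequences with every symbol (gap included) at probability 1/q."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    from .alignment import AMINO_ACID_ALPHABET

    alphabet = AMINO_ACID_ALPHABET[:q] if q <= 21 else "".join(chr(65 + i) for i in range(q))
    return EncodedAlignment(rng.integers(0, q, size=(n, N)), alphabet=alphabet)


def _target_energies(model: EnergyModel, codes: np.ndarray, k_target: int, seed: int) -> np.ndarray:
    """Original-model energies; uses K-sample importance estimates when the
    model's energies are themselves estimates."""
    if model.energy_is_estimate and hasattr(model, "energy_importance"):
        return model.energy_importance(codes, K=k_target, seed=seed)
    return model.energy(codes)


def mse_loss(sample_set: EnergySampleSet, candidate) -> float:
    """Mean squared energy error of a candidate model on a sample set."""
    pred = candidate.energy(sample_set.sequences.codes)
    return float(np.mean((sample_set.energies - pred) ** 2))


# ---------------------------------------------------------------------------
# estimators


class PairwiseDistiller(BaseEstimator, RegressorMixin):
    """Least-squares regression of energies onto the pairwise parameterization.

    fit(X, y) takes integer-coded sequences X of shape (n, N) (or an
    :class:`EncodedAlignment`) and target energies y; predict(X) returns the
    fitted model's energies.  ``solver="lstsq"`` builds the one-hot design
    matrix and solves the (weighted) normal system by pseudo-inverse —
    exact, but only for modest n x parameter sizes; ``solver="adam"`` runs
    the stochastic protocol of :class:`ExtractionConfig`.

    Attributes: ``model_`` (the fitted :class:`PairwiseModel` or
    :class:`IndependentModel`), ``loss_`` (achieved training MSE),
    ``history_`` (adam solver log).
    """

    family = "pairwise"

    def __init__(self, solver: str = "lstsq", config: Optional[ExtractionConfig] = None):
        self.solver = solver
        self.config = config

    def _resolve_config(self) -> ExtractionConfig:
        cfg = self.config or ExtractionConfig()
        if cfg.family != self.family:
            cfg = ExtractionConfig(**{**cfg.__dict__, "family": self.family})
        return cfg

    def fit(self, X, y, sample_weight=None, mix_model: EnergyModel | None = None):
        codes = X.codes if isinstance(X, EncodedAlignment) else np.atleast_2d(np.asarray(X))
        y = np.asarray(y, dtype=float)
        q = X.q if isinstance(X, EncodedAlignment) else int(codes.max()) + 1
        if self.solver == "lstsq":
            self.model_, self.loss_ = _lstsq_fit(codes, y, q, self.family, sample_weight)
            self.history_ = None
        elif self.solver == "adam":
            cfg = self._resolve_config()
            self.model_, self.loss_, self.history_ = _adam_fit(
                codes, y, q, cfg, mix_model=mix_model
            )
        else:
            raise ValueError(f"unknown solver {self.solver!r}")
        return self

    def predict(self, X) -> np.ndarray:
        codes = X.codes if isinstance(X, EncodedAlignment) else np.atleast_2d(np.asarray(X))
        return self.model_.energy(codes)


class IndependentDistiller(PairwiseDistiller):
    """Profile-model distillation: same objective with the couplings fixed to 0."""

    family = "independent"


# ---------------------------------------------------------------------------
# solvers


def _design_matrix(codes: np.ndarray, q: int, family: str) -> np.ndarray:
    """One-hot features phi(s) with E_candidate(s) = -(phi @ theta).

    Column order: constant, fields (N*q), then couplings (pair-major, q*q).
    """
    n, N = codes.shape
    cols = 1 + N * q + (n_pairs(N) * q * q if family == "pairwise" else 0)
    phi = np.zeros((n, cols))
    phi[:, 0] = 1.0
    rows = np.arange(n)
    for i in range(N):
        phi[rows, 1 + i * q + codes[:, i]] = 1.0
    if family == "pairwise":
        base = 1 + N * q
        for p, (i, j) in enumerate(pair_list(N)):
            phi[rows, base + p * q * q + codes[:, i] * q + codes[:, j]] = 1.0
    return phi


def _theta_to_model(theta: np.ndarray, N: int, q: int, family: str):
    C = float(theta[0])
    h = theta[1 : 1 + N * q].reshape(N, q)
    if family == "independent":
        return IndependentModel(h=h, C=C)
    J = theta[1 + N * q :].reshape(n_pairs(N), q, q)
    return PairwiseModel(h=h, J=J, C=C)


def _lstsq_fit(codes, y, q, family, sample_weight=None):
    n, N = codes.shape
    phi = _design_matrix(codes, q, family)
    if sample_weight is not None:
        sw = np.sqrt(np.asarray(sample_weight, dtype=float))
        A, b = phi * sw[:, None], -y * sw
    else:
        A, b = phi, -y
    theta, *_ = np.linalg.lstsq(A, b, rcond=None)
    model = _theta_to_model(theta, N, q, family)
    pred = -(phi @ theta)
    if sample_weight is not None:
        w = np.asarray(sample_weight, dtype=float)
        loss = float(np.sum(w * (y - pred) ** 2) / np.sum(w))
    else:
        loss = float(np.mean((y - pred) ** 2))
    return model, loss


def _batch_energy(h, J, C, codes, pairs):
    out = h[np.arange(codes.shape[1]), codes].sum(axis=1)
    for p, (i, j) in enumerate(pairs):
        out += J[p][codes[:, i], codes[:, j]]
    return -(out + C)


def _adam_fit(codes, energies, q, cfg: ExtractionConfig, mix_model: EnergyModel | None = None):
    """The stochastic extraction loop (see module docstring)."""
    n, N = codes.shape
    pairs = pair_list(N)
    rng = np.random.default_rng(cfg.seed)
    h = np.zeros((N, q))
    J = np.zeros((n_pairs(N), q, q))
    C = 0.0
    m_h, v_h = np.zeros_like(h), np.zeros_like(h)
    m_J, v_J = np.zeros_like(J), np.zeros_like(J)
    m_C = v_C = 0.0
    b1, b2 = cfg.adam_betas
    eps = 1e-8
    fit_J = cfg.family == "pairwise"

    ema = None
    best_ema = np.inf
    best = (h.copy(), J.copy(), C)
    best_step = 0
    losses, emas = [], []
    B = cfg.batch_size

    for step in range(1, cfg.max_steps + 1):
        pick = rng.integers(0, n, size=B)
        batch = codes[pick].copy()
        y = energies[pick].copy()
        if cfg.uniform_mix_prob > 0 and mix_model is not None:
            mask = rng.random(B) < cfg.uniform_mix_prob
            k = int(mask.sum())
            if k:
                fresh = rng.integers(0, q, size=(k, N))
                batch[mask] = fresh
                y[mask] = _target_energies(
                    mix_model, fresh, cfg.k_target, seed=int(rng.integers(2**31))
                )
        pred = _batch_energy(h, J, C, batch, pairs)
        r = pred - y
        loss = float(np.mean(r**2))
        losses.append(loss)
        # gradient of the batch MSE; dE/dtheta = -1 at the active one-hot slot
        coef = -2.0 * r / B
        g_C = float(coef.sum())
        g_h = np.zeros_like(h)
        for i in range(N):
            g_h[i] = np.bincount(batch[:, i], weights=coef, minlength=q)
        if fit_J:
            g_J = np.empty_like(J)
            for p, (i, j) in enumerate(pairs):
                g_J[p] = np.bincount(
                    batch[:, i] * q + batch[:, j], weights=coef, minlength=q * q
                ).reshape(q, q)
        t = step
        m_h = b1 * m_h + (1 - b1) * g_h
        v_h = b2 * v_h + (1 - b2) * g_h**2
        h -= cfg.step_size * (m_h / (1 - b1**t)) / (np.sqrt(v_h / (1 - b2**t)) + eps)
        if fit_J:
            m_J = b1 * m_J + (1 - b1) * g_J
            v_J = b2 * v_J + (1 - b2) * g_J**2
            J -= cfg.step_size * (m_J / (1 - b1**t)) / (np.sqrt(v_J / (1 - b2**t)) + eps)
        m_C = b1 * m_C + (1 - b1) * g_C
        v_C = b2 * v_C + (1 - b2) * g_C**2
        C -= cfg.step_size * (m_C / (1 - b1**t)) / (np.sqrt(v_C / (1 - b2**t)) + eps)

        ema = loss if ema is None else cfg.ema_factor * ema + (1 - cfg.ema_factor) * loss
        emas.append(ema)
        if ema < best_ema:
            best_ema = ema
            best = (h.copy(), J.copy() if fit_J else J, C)
            best_step = step
        if step - best_step >= cfg.patience_steps:
            break
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite extraction loss at step {step}")

    h_b, J_b, C_b = best
    if cfg.family == "independent":
        model = IndependentModel(h=h_b, C=C_b)
    else:
        model = PairwiseModel(h=h_b, J=J_b, C=C_b)
    log = {
        "losses": np.array(losses),
        "ema": np.array(emas),
        "best_step": best_step,
        "best_ema": best_ema,
        "steps_run": len(losses),
    }
    return model, best_ema, log


# ---------------------------------------------------------------------------
# the three extraction routes


def extract_exact(
    model: EnergyModel,
    weights: np.ndarray | None = None,
    family: str = "pairwise",
    cap: int = 10**6,
):
    """Global MSE minimizer over a full enumeration of sequence space.

    ``weights`` is a nonnegative vector over all q^N sequences in
    lexicographic order (uniform when None).  Returns ``(fitted_model,
    achieved_loss)``; gauge-null directions are resolved by pseudo-inverse.
    """
    codes = enumerate_sequences(model.N, model.q, cap)
    y = model.energy(codes)
    if weights is None:
        weights = np.full(len(codes), 1.0 / len(codes))
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(codes),) or np.any(weights < 0):
            raise ValueError("weights must be nonnegative, one per enumerated sequence")
        weights = weights / weights.sum()
    return _lstsq_fit(codes, y, model.q, family, sample_weight=weights)


def extract_uniform_closed_form(
    model: EnergyModel,
    n_samples: int,
    seed: int = 0,
    family: str = "pairwise",
    k_target: int = 5000,
):
    """Closed-form D = U extraction from conditional means of uniform samples.

    The constant is (minus) the grand mean energy, fields come from
    single-site conditional means and couplings from pair conditional means
    with the lower-order terms subtracted — the empirical order-<=2 zero-sum
    expansion.  Empty conditional cells fall back to the grand mean (a zero
    coefficient).  The result is projected to the exact zero-sum gauge.
    Returns ``(fitted_model, sample_set)``.
    """
    N, q = model.N, model.q
    aln = sample_uniform(N, q, n_samples, seed)
    codes = aln.codes
    E = _target_energies(model, codes, k_target, seed=seed + 1)
    grand = E.mean()
    f1 = np.zeros((N, q))
    counts1 = np.zeros((N, q))
    for i in range(N):
        counts1[i] = np.bincount(codes[:, i], minlength=q)
        sums = np.bincount(codes[:, i], weights=E, minlength=q)
        filled = counts1[i] > 0
        f1[i, filled] = sums[filled] / counts1[i, filled] - grand
    h = -f1
    C = -grand
    estimator = (
        {"kind": "is", "K": k_target, "seed": seed + 1}
        if model.energy_is_estimate
        else {"kind": "exact"}
    )
    sset = EnergySampleSet(aln, E, source="U", estimator=estimator)
    if family == "independent":
        return to_zero_sum_gauge(IndependentModel(h=h, C=C)), sset
    J = np.zeros((n_pairs(N), q, q))
    for p, (i, j) in enumerate(pair_list(N)):
        idx = codes[:, i] * q + codes[:, j]
        cnt = np.bincount(idx, minlength=q * q).reshape(q, q)
        sums = np.bincount(idx, weights=E, minlength=q * q).reshape(q, q)
        cond = np.where(cnt > 0, sums / np.maximum(cnt, 1), grand)
        J[p] = -(cond - f1[i][:, None] - f1[j][None, :] - grand)
    return to_zero_sum_gauge(PairwiseModel(h=h, J=J, C=C)), sset


def prepare_sample_set(
    model: EnergyModel, config: ExtractionConfig, sample_set: EnergySampleSet | None = None
) -> EnergySampleSet:
    """Materialize the regression data (sequences + energies) for extraction."""
    if config.distribution == "explicit":
        if sample_set is None:
            raise ValueError("distribution='explicit' requires a sample_set")
        return sample_set
    if config.distribution == "U":
        aln = sample_uniform(model.N, model.q, config.n_samples, config.seed)
    else:
        aln = model.sample(config.n_samples, seed=config.seed)
    E = _target_energies(model, aln.codes, config.k_target, seed=config.seed + 1)
    estimator = (
        {"kind": "is", "K": config.k_target, "seed": config.seed + 1}
        if model.energy_is_estimate
        else {"kind": "exact"}
    )
    return EnergySampleSet(aln, E, source=config.distribution, estimator=estimator)


def extract_sgd(
    model: EnergyModel,
    config: ExtractionConfig,
    sample_set: EnergySampleSet | None = None,
):
    """The full stochastic protocol; returns ``(fitted_model, training_log)``."""
    data = prepare_sample_set(model, config, sample_set)
    dist = PairwiseDistiller if config.family == "pairwise" else IndependentDistiller
    est = dist(solver="adam", config=config)
    est.fit(data.sequences, data.energies, mix_model=model)
    return est.model_, est.history_
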