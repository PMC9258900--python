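"""Energy-based-model contract, pairwise/independent models, gauges and oracles.

Every generative model here is viewed through its energy E(s) = -log p(s)
(up to an additive constant).  The normalization constant is a sum over q^N
terms and is never computed except by explicit enumeration on toy sizes.

A *pairwise* (Potts) model has

    E_pw(s) = - sum_{i<j} J_ij(s_i, s_j) - sum_i h_i(s_i) - C,

with couplings J, fields h and a constant C.  An *independent* (profile)
model is the special case J = 0.  The decomposition of a fixed energy into
(C, h, J, higher orders) is not unique (gauge freedom); the *zero-sum* gauge
— every tensor sums to zero along each amino-acid axis — is the canonical
choice that pushes as much mass as possible into low orders, and coincides
with the uniform-weighted orthogonal (Möbius) expansion computed by
:func:`mobius_zero_sum_expansion`.
"""

from __future__ import annotations

import itertools
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from .alignment import AMINO_ACID_ALPHABET, EncodedAlignment

ENUMERATION_CAP = 10**6


# ---------------------------------------------------------------------------
# contract


class EnergyModel(ABC):
    """Behavioral contract: exact or estimated energies plus a sampler.

    Implementations expose ``N`` (sequence length), ``q`` (alphabet size),
    ``energy(codes)`` (vectorized, one real per sequence) and
    ``sample(n, seed)``.  ``energy_is_estimate`` flags stochastic estimators
    (e.g. importance sampling); estimates must still be deterministic given
    their seed.
    """

    N: int
    q: int
    energy_is_estimate: bool = False
    alphabet: str = AMINO_ACID_ALPHABET

    @abstractmethod
    def energy(self, codes: np.ndarray) -> np.ndarray:
        """Energies for sequences ``codes`` of shape (n, N) or (N,)."""

    @abstractmethod
    def sample(self, n: int, seed: int = 0) -> EncodedAlignment:
        """Draw ``n`` sequences from the model distribution."""

    def _validate(self, codes: np.ndarray) -> np.ndarray:
        codes = np.atleast_2d(np.asarray(codes, dtype=np.int64))
        if codes.shape[1] != self.N:
            raise ValueError(f"sequences have length {codes.shape[1]}, model expects {self.N}")
        if codes.size and (codes.min() < 0 or codes.max() >= self.q):
            raise ValueError(f"symbol codes must lie in [0, {self.q})")
        return codes

    def _alphabet_for(self) -> str:
        if len(self.alphabet) == self.q:
            return self.alphabet
        return AMINO_ACID_ALPHABET[: self.q] if self.q <= 21 else "".join(
            chr(65 + i) for i in range(self.q)
        )


def n_pairs(N: int) -> int:
    return N * (N - 1) // 2


def pair_list(N: int) -> list[tuple[int, int]]:
    """Ordered (i, j) with i < j, matching the flat coupling storage order."""
    return [(i, j) for i in range(N) for j in range(i + 1, N)]


def pair_index(i: int, j: int, N: int) -> int:
    if i > j:
        i, j = j, i
    return i * N - i * (i + 1) // 2 + (j - i - 1)


# ---------------------------------------------------------------------------
# pairwise / independent models


@dataclass
class PairwiseModel(EnergyModel):
    """Potts model E(s) = -sum_{i<j} J_ij(s_i,s_j) - sum_i h_i(s_i) - C.

    Couplings are stored once per unordered pair in ``J`` of shape
    (N(N-1)/2, q, q), row index following :func:`pair_list`; access for j < i
    is the transpose ``J_ij(a, b) = J_ji(b, a)``.
    """

    h: np.ndarray
    J: np.ndarray
    C: float = 0.0
    gauge: str = "none"
    alphabet: str = AMINO_ACID_ALPHABET

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        N, q = self.h.shape
        if self.J.shape != (n_pairs(N), q, q):
            raise ValueError(f"J must have shape ({n_pairs(N)}, {q}, {q}), got {self.J.shape}")
        if not (np.all(np.isfinite(self.h)) and np.all(np.isfinite(self.J)) and np.isfinite(self.C)):
            raise ValueError("model parameters must be finite")
        self.N, self.q = N, q

    def coupling(self, i: int, j: int) -> np.ndarray:
        """J_ij as a (q, q) matrix indexed (a at i, b at j); symmetrized access."""
        if i == j:
            raise ValueError("coupling requires i != j")
        block = self.J[pair_index(i, j, self.N)]
        return block if i < j else block.T

    def energy(self, codes: np.ndarray) -> np.ndarray:
        codes = self._validate(codes)
        out = self.h[np.arange(self.N), codes].sum(axis=1)
        for p, (i, j) in enumerate(pair_list(self.N)):
            out += self.J[p][codes[:, i], codes[:, j]]
        return -(out + self.C)

    def sample(self, n: int, seed: int = 0) -> EncodedAlignment:
        """Exact categorical sampling via enumeration (toy sizes only).

        For models too large to enumerate use the Gibbs sampler in
        :func:`pairdistill.synthetic.sample_model`.
        """
        codes = enumerate_sequences(self.N, self.q)
        logp = -self.energy(codes)
        logp -= logp.max()
        p = np.exp(logp)
        p /= p.sum()
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(codes), size=n, p=p)
        return EncodedAlignment(codes[idx], alphabet=self._alphabet_for())


@dataclass
class IndependentModel(EnergyModel):
    """Profile model E(s) = -sum_i h_i(s_i) - C; the distribution factorizes."""

    h: np.ndarray
    C: float = 0.0
    gauge: str = "none"
    alphabet: str = AMINO_ACID_ALPHABET

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if not (np.all(np.isfinite(self.h)) and np.isfinite(self.C)):
            raise ValueError("model parameters must be finite")
        self.N, self.q = self.h.shape

    def energy(self, codes: np.ndarray) -> np.ndarray:
        codes = self._validate(codes)
        return -(self.h[np.arange(self.N), codes].sum(axis=1) + self.C)

    def site_probabilities(self) -> np.ndarray:
        """Per-position marginals p_i(a) ∝ exp(h_i(a)), shape (N, q)."""
        z = self.h - self.h.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def sample(self, n: int, seed: int = 0) -> EncodedAlignment:
        rng = np.random.default_rng(seed)
        p = self.site_probabilities()
        u = rng.random((n, self.N))
        codes = (u[:, :, None] > np.cumsum(p, axis=1)[None, :, :]).sum(axis=2)
        return EncodedAlignment(codes, alphabet=self._alphabet_for())

    def as_pairwise(self) -> PairwiseModel:
        """Embed with all couplings zero."""
        return PairwiseModel(
            h=self.h.copy(),
            J=np.zeros((n_pairs(self.N), self.q, self.q)),
            C=self.C,
            gauge=self.gauge,
            alphabet=self.alphabet,
        )


def pairwise_energy(model: PairwiseModel, codes: np.ndarray) -> np.ndarray:
    return model.energy(codes)


def independent_energy(model: IndependentModel, codes: np.ndarray) -> np.ndarray:
    return model.energy(codes)


def parameter_count(N: int, q: int, family: str = "pairwise") -> int:
    """Number of free parameters (fields + couplings + constant).

    pairwise: N*q + N(N-1)/2 * q^2 + 1; independent: N*q + 1.  At the largest
    protein-domain length used in practice here (N=77, q=21) the pairwise
    count is 1,291,984, i.e. about 1.3e6.
    """
    if N < 1 or q < 2:
        raise ValueError("need N >= 1 and q >= 2")
    if family == "pairwise":
        return N * q + n_pairs(N) * q * q + 1
    if family == "independent":
        return N * q + 1
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# gauge fixing


def to_zero_sum_gauge(model: PairwiseModel | IndependentModel):
    """Return an energy-equivalent model in the zero-sum (Ising) gauge.

    Every coupling block sums to zero over each amino-acid index and every
    field vector sums to zero; the displaced means are folded into the fields
    and the constant, so all energies are unchanged.  Idempotent up to float
    tolerance.
    """
    if isinstance(model, IndependentModel):
        means = model.h.mean(axis=1)
        return IndependentModel(
            h=model.h - means[:, None],
            C=model.C + means.sum(),
            gauge="zero_sum",
            alphabet=model.alphabet,
        )
    N, q = model.N, model.q
    h = model.h.copy()
    J = model.J.copy()
    C = model.C
    for p, (i, j) in enumerate(pair_list(N)):
        block = J[p]
        row = block.mean(axis=1)   # per a at i
        col = block.mean(axis=0)   # per b at j
        grand = block.mean()
        J[p] = block - row[:, None] - col[None, :] + grand
        h[i] += row - grand
        h[j] += col - grand
        C += grand
    means = h.mean(axis=1)
    h -= means[:, None]
    C += means.sum()
    return PairwiseModel(h=h, J=J, C=C, gauge="zero_sum", alphabet=model.alphabet)


# ---------------------------------------------------------------------------
# enumeration oracles


def enumerate_sequences(N: int, q: int, cap: int = ENUMERATION_CAP) -> np.ndarray:
    """All q^N sequences in lexicographic order (position 0 most significant)."""
    total = q**N
    if total > cap:
        raise ValueError(f"q^N = {total} exceeds enumeration cap {cap}")
    k = np.arange(total)
    powers = q ** np.arange(N - 1, -1, -1)
    return (k[:, None] // powers[None, :]) % q


def enumerate_energies(model: EnergyModel, cap: int = ENUMERATION_CAP) -> np.ndarray:
    """Energies of all q^N sequences, lexicographic order."""
    return model.energy(enumerate_sequences(model.N, model.q, cap))


@dataclass
class ExpansionCoefficients:
    """Interaction expansion E(s) = sum_{L subset of positions} f_L(s_L).

    ``coeffs`` maps a sorted position tuple L to a tensor over the amino-acid
    assignments at those positions; the empty tuple maps to the scalar f_0.
    The expansion is not unique; :func:`mobius_zero_sum_expansion` produces
    the zero-sum (orthogonal-under-uniform) representative, but any
    assignment of tensors — e.g. the degenerate f_I(s) = E(s) — is accepted.
    """

    N: int
    q: int
    coeffs: dict[tuple[int, ...], np.ndarray]
    max_order: int

    def reconstruct(self, codes: np.ndarray) -> np.ndarray:
        codes = np.atleast_2d(np.asarray(codes, dtype=np.int64))
        out = np.zeros(len(codes))
        for L, tensor in self.coeffs.items():
            if len(L) == 0:
                out += float(tensor)
            else:
                out += tensor[tuple(codes[:, pos] for pos in L)]
        return out

    def truncate(self, order: int) -> "ExpansionCoefficients":
        kept = {L: t for L, t in self.coeffs.items() if len(L) <= order}
        return ExpansionCoefficients(self.N, self.q, kept, min(order, self.max_order))

    def order_norm(self, order: int) -> float:
        """Sum of squared coefficients at the given interaction order."""
        return float(
            sum(np.sum(np.asarray(t) ** 2) for L, t in self.coeffs.items() if len(L) == order)
        )

    def to_pairwise(self, alphabet: str | None = None) -> PairwiseModel:
        """Order-<=2 truncation as a PairwiseModel (in the zero-sum gauge when
        the coefficients come from :func:`mobius_zero_sum_expansion`)."""
        h = np.zeros((self.N, self.q))
        J = np.zeros((n_pairs(self.N), self.q, self.q))
        C = -float(self.coeffs.get((), 0.0))
        for L, tensor in self.coeffs.items():
            if len(L) == 1:
                h[L[0]] = -tensor
            elif len(L) == 2:
                J[pair_index(L[0], L[1], self.N)] = -tensor
        return PairwiseModel(
            h=h, J=J, C=C, gauge="zero_sum", alphabet=alphabet or AMINO_ACID_ALPHABET[: self.q]
        )


def mobius_zero_sum_expansion(
    model: EnergyModel, max_order: int | None = None, cap: int = ENUMERATION_CAP
) -> ExpansionCoefficients:
    """Brute-force orthogonal interaction expansion under the uniform measure.

    f_0 is the mean energy over all q^N sequences; f_i(a) the conditional mean
    given s_i = a minus f_0; f_ij(a, b) the pair conditional mean minus all
    lower-order terms, and so on recursively.  Keeping all orders reconstructs
    E exactly; every tensor sums to zero along each of its axes.
    """
    N, q = model.N, model.q
    E = enumerate_energies(model, cap).reshape((q,) * N)
    if max_order is None:
        max_order = N
    coeffs: dict[tuple[int, ...], np.ndarray] = {(): np.asarray(E.mean())}
    for order in range(1, max_order + 1):
        for L in itertools.combinations(range(N), order):
            other = tuple(i for i in range(N) if i not in L)
            cond = E.mean(axis=other) if other else E.copy()
            f = np.asarray(cond, dtype=float)
            for sub_order in range(order):
                for sub in itertools.combinations(L, sub_order):
                    t = coeffs[sub]
                    if sub_order == 0:
                        f = f - float(t)
                    else:
                        axes = tuple(L.index(p) for p in sub)
                        shape = [1] * order
                        for ax in axes:
                            shape[ax] = q
                        f = f - t.reshape(shape)
            coeffs[L] = f
    return ExpansionCoefficients(N=N, q=q, coeffs=coeffs, max_order=max_order)


# ---------------------------------------------------------------------------
# serialization (flat key/value container with shape metadata)


def save_model(model, path) -> None:
    """Write a PairwiseModel or IndependentModel to a flat .npz container."""
    meta = dict(alphabet=model.alphabet, gauge=getattr(model, "gauge", "none"))
    if isinstance(model, PairwiseModel):
        np.savez(path, kind="pairwise", h=model.h, J=model.J, C=model.C, **meta)
    elif isinstance(model, IndependentModel):
        np.savez(path, kind="independent", h=model.h, C=model.C, **meta)
    else:
        raise TypeError(f"cannot serialize {type(model).__name__} here")


def load_model(path):
    """Inverse of :func:`save_model`; round-trips all parameters exactly."""
    with np.load(path, allow_pickle=False) as data:
        kind = str(data["kind"])
        alphabet = str(data["alphabet"])
        gauge = str(data["gauge"])
        if kind == "pairwise":
            return PairwiseModel(
                h=data["h"], J=data["J"], C=float(data["C"]), gauge=gauge, alphabet=alphabet
            )
        if kind == "independent":
            return IndependentModel(
                h=data["h"], C=float(data["C"]), gauge=gauge, alphabet=alphabet
            )
    raise ValueError(f"unknown model kind {kind!r}")
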