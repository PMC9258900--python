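"""One-hidden-layer variational autoencoder over one-hot protein sequences.

Encoder: h_enc = tanh(W_enc s + b_enc); q(z|s) = N(mu, diag(sigma^2)) with
mu = W_mu h_enc + b_mu and log sigma^2 = W_sigma h_enc + b_sigma.
Decoder: h_dec = tanh(W_dec z + b_dec); p(s|z) factorizes over positions,
each a softmax of W_s h_dec + b_s restricted to that position's q logits.
The prior on z is standard normal.

Training runs full-batch gradient descent (optionally Adam) on the
reweighted ELBO with weight decay on the weight matrices; all gradients are
derived analytically (finite-difference-checked in the test suite).

The marginal likelihood is intractable, so energies E(s) = -log p(s) are
importance-sampling estimates with the encoder as proposal:

    p(s) ~= 1/K sum_k p(s|z_k) N(z_k; 0, I) / q(z_k|s),   z_k ~ q(z|s),

computed in log space with log-sum-exp; the default K is 5000.  Energies
from this model therefore carry the "estimated" flag and record (K, seed).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .alignment import AMINO_ACID_ALPHABET, EncodedAlignment
from .energy import EnergyModel

_WEIGHT_KEYS = ("W_enc", "W_mu", "W_sigma", "W_dec", "W_s")
_BIAS_KEYS = ("b_enc", "b_mu", "b_sigma", "b_dec", "b_s")
_ALL_KEYS = _WEIGHT_KEYS + _BIAS_KEYS


def _one_hot(codes: np.ndarray, q: int) -> np.ndarray:
    n, N = codes.shape
    X = np.zeros((n, N * q))
    X[np.arange(n)[:, None], np.arange(N)[None, :] * q + codes] = 1.0
    return X


class SequenceVAE(BaseEstimator, EnergyModel):
    """Variational autoencoder with a single hidden layer in encoder and decoder.

    Parameters
    ----------
    hidden : int, default=40
        Hidden units (same number in encoder and decoder).
    latent : int, default=5
        Latent dimension d.
    weight_decay : float, default=0.01
        L2 penalty on the weight matrices (biases are not decayed).
    steps : int, default=2000
        Full-batch gradient steps.
    lr : float, default=0.01
        Step size.
    optimizer : {"gd", "adam"}, default="gd"
    n_mc : int, default=1
        Monte-Carlo samples per ELBO evaluation during training.
    is_samples : int, default=5000
        Importance samples K used by :meth:`energy`.
    seed : int, default=0
        Seed for initialization and the reparameterization noise.
    """

    energy_is_estimate = True

    def __init__(
        self,
        hidden: int = 40,
        latent: int = 5,
        weight_decay: float = 0.01,
        steps: int = 2000,
        lr: float = 0.01,
        optimizer: str = "gd",
        n_mc: int = 1,
        is_samples: int = 5000,
        seed: int = 0,
        n_symbols: int | None = None,
    ):
        self.hidden = hidden
        self.latent = latent
        self.weight_decay = weight_decay
        self.steps = steps
        self.lr = lr
        self.optimizer = optimizer
        self.n_mc = n_mc
        self.is_samples = is_samples
        self.seed = seed
        self.n_symbols = n_symbols

    # -- construction --------------------------------------------------------

    @classmethod
    def from_parameters(cls, params: dict, N: int, q: int, alphabet: str | None = None):
        """Build a usable model from an explicit parameter dictionary."""
        model = cls(hidden=params["W_enc"].shape[0], latent=params["W_mu"].shape[0])
        model.params_ = {k: np.asarray(params[k], dtype=float) for k in _ALL_KEYS}
        model.N, model.q = N, q
        model.alphabet = alphabet or AMINO_ACID_ALPHABET[:q]
        return model

    def _init_params(self, N: int, q: int, rng: np.random.Generator) -> dict:
        H, d, D = self.hidden, self.latent, N * q

        def glorot(shape):
            s = np.sqrt(2.0 / (shape[0] + shape[1]))
            return rng.normal(0.0, s, size=shape)

        return {
            "W_enc": glorot((H, D)),
            "b_enc": np.zeros(H),
            "W_mu": glorot((d, H)),
            "b_mu": np.zeros(d),
            "W_sigma": glorot((d, H)),
            "b_sigma": np.zeros(d),
            "W_dec": glorot((H, d)),
            "b_dec": np.zeros(H),
            "W_s": glorot((D, H)),
            "b_s": np.zeros(D),
        }

    # -- deterministic pieces ------------------------------------------------

    def encode(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters (mu, log sigma^2), each (n, latent)."""
        codes = self._validate(codes)
        X = _one_hot(codes, self.q)
        p = self.params_
        h_enc = np.tanh(X @ p["W_enc"].T + p["b_enc"])
        return h_enc @ p["W_mu"].T + p["b_mu"], h_enc @ p["W_sigma"].T + p["b_sigma"]

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Per-position probability vectors, shape (..., N, q); rows sum to 1."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        p = self.params_
        h_dec = np.tanh(z @ p["W_dec"].T + p["b_dec"])
        logits = (h_dec @ p["W_s"].T + p["b_s"]).reshape(len(z), self.N, self.q)
        logits -= logsumexp(logits, axis=2, keepdims=True)
        return np.exp(logits)

    def _decoder_logprob(self, z: np.ndarray, codes: np.ndarray) -> np.ndarray:
        """log p(s|z) for paired rows of z (m, d) and codes (m, N)."""
        p = self.params_
        h_dec = np.tanh(z @ p["W_dec"].T + p["b_dec"])
        logits = (h_dec @ p["W_s"].T + p["b_s"]).reshape(len(z), self.N, self.q)
        logits -= logsumexp(logits, axis=2, keepdims=True)
        return logits[np.arange(len(z))[:, None], np.arange(self.N)[None, :], codes].sum(axis=1)

    # -- ELBO and training ---------------------------------------------------

    def elbo(self, codes: np.ndarray, n_mc: int = 1, seed: int = 0) -> np.ndarray:
        """Per-sequence reparameterized ELBO estimate (KL term in closed form)."""
        codes = self._validate(codes)
        mu, lv = self.encode(codes)
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal((n_mc, *mu.shape))
        z = mu[None] + np.exp(0.5 * lv)[None] * eps
        flat_codes = np.broadcast_to(codes, (n_mc, *codes.shape)).reshape(-1, self.N)
        recon = self._decoder_logprob(z.reshape(-1, self.latent), flat_codes)
        recon = recon.reshape(n_mc, len(codes)).mean(axis=0)
        kl = 0.5 * np.sum(np.exp(lv) + mu**2 - 1.0 - lv, axis=1)
        return recon - kl

    def _loss_and_grads(self, X, codes, w, rng):
        """Negative weighted ELBO plus weight decay, with analytic gradients."""
        p = self.params_
        n, K = len(codes), self.n_mc
        H, d, N, q = self.hidden, self.latent, self.N, self.q

        A = X @ p["W_enc"].T + p["b_enc"]
        h_enc = np.tanh(A)
        mu = h_enc @ p["W_mu"].T + p["b_mu"]
        lv = h_enc @ p["W_sigma"].T + p["b_sigma"]
        eps = rng.standard_normal((K, n, d))
        z = mu[None] + np.exp(0.5 * lv)[None] * eps

        z_flat = z.reshape(K * n, d)
        B = z_flat @ p["W_dec"].T + p["b_dec"]
        h_dec = np.tanh(B)
        logits = (h_dec @ p["W_s"].T + p["b_s"]).reshape(K * n, N, q)
        lse = logsumexp(logits, axis=2, keepdims=True)
        logp = logits - lse
        flat_codes = np.broadcast_to(codes, (K, n, N)).reshape(K * n, N)
        rows = np.arange(K * n)[:, None]
        recon = logp[rows, np.arange(N)[None, :], flat_codes].sum(axis=1)
        recon = recon.reshape(K, n).mean(axis=0)
        kl = 0.5 * np.sum(np.exp(lv) + mu**2 - 1.0 - lv, axis=1)
        loss = -float(np.dot(w, recon - kl))

        # backward pass (gradient of the minimized loss)
        onehot3 = np.zeros((K * n, N, q))
        onehot3[rows, np.arange(N)[None, :], flat_codes] = 1.0
        w_rep = np.broadcast_to(w / K, (K, n)).reshape(K * n)
        dlogits = (np.exp(logp) - onehot3) * w_rep[:, None, None]
        dlogits_flat = dlogits.reshape(K * n, N * q)
        g = {}
        g["W_s"] = dlogits_flat.T @ h_dec
        g["b_s"] = dlogits_flat.sum(axis=0)
        dB = (dlogits_flat @ p["W_s"]) * (1.0 - h_dec**2)
        g["W_dec"] = dB.T @ z_flat
        g["b_dec"] = dB.sum(axis=0)
        dz = (dB @ p["W_dec"]).reshape(K, n, d)
        dmu = dz.sum(axis=0) + w[:, None] * mu
        dlv = (dz * eps).sum(axis=0) * 0.5 * np.exp(0.5 * lv) + w[:, None] * 0.5 * (np.exp(lv) - 1.0)
        g["W_mu"] = dmu.T @ h_enc
        g["b_mu"] = dmu.sum(axis=0)
        g["W_sigma"] = dlv.T @ h_enc
        g["b_sigma"] = dlv.sum(axis=0)
        dA = (dmu @ p["W_mu"] + dlv @ p["W_sigma"]) * (1.0 - h_enc**2)
        g["W_enc"] = dA.T @ X
        g["b_enc"] = dA.sum(axis=0)

        for k in _WEIGHT_KEYS:
            loss += self.weight_decay * float(np.sum(p[k] ** 2))
            g[k] += 2.0 * self.weight_decay * p[k]
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite VAE training loss")
        return loss, g

    def fit(self, X, y=None, sample_weight=None) -> "SequenceVAE":
        """Full-batch gradient descent on the reweighted ELBO with weight decay."""
        if isinstance(X, EncodedAlignment):
            codes, alphabet = X.codes, X.alphabet
            if sample_weight is None and X.weights is not None:
                sample_weight = X.weights
        else:
            codes, alphabet = np.atleast_2d(np.asarray(X, dtype=np.int64)), None
        n, N = codes.shape
        if n < 2:
            raise ValueError("need at least 2 sequences to fit")
        q = self.n_symbols or (len(alphabet) if alphabet else int(codes.max()) + 1)
        self.N, self.q = N, q
        self.alphabet = alphabet or AMINO_ACID_ALPHABET[:q]
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        w = w / w.sum()

        rng = np.random.default_rng(self.seed)
        self.params_ = self._init_params(N, q, rng)
        Xoh = _one_hot(codes, q)

        if self.optimizer == "adam":
            m = {k: np.zeros_like(v) for k, v in self.params_.items()}
            v = {k: np.zeros_like(val) for k, val in self.params_.items()}
            b1, b2, eps_ = 0.9, 0.999, 1e-8
        elif self.optimizer != "gd":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

        self.loss_history_ = []
        for step in range(1, self.steps + 1):
            loss, g = self._loss_and_grads(Xoh, codes, w, rng)
            self.loss_history_.append(loss)
            if self.optimizer == "gd":
                for k in _ALL_KEYS:
                    self.params_[k] -= self.lr * g[k]
            else:
                for k in _ALL_KEYS:
                    m[k] = b1 * m[k] + (1 - b1) * g[k]
                    v[k] = b2 * v[k] + (1 - b2) * g[k] ** 2
                    mhat = m[k] / (1 - b1**step)
                    vhat = v[k] / (1 - b2**step)
                    self.params_[k] -= self.lr * mhat / (np.sqrt(vhat) + eps_)
        return self

    # -- sampling and energies ----------------------------------------------

    def sample(self, n: int, seed: int = 0) -> EncodedAlignment:
        """One z ~ N(0, I) per sequence; positions sampled independently."""
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.latent))
        probs = self.decode(z)
        u = rng.random((n, self.N, 1))
        codes = (u > np.cumsum(probs, axis=2)).sum(axis=2)
        return EncodedAlignment(codes, alphabet=self._alphabet_for())

    def energy_importance(
        self, codes: np.ndarray, K: int = 5000, seed: int = 0, chunk: int | None = None
    ) -> np.ndarray:
        """Importance-sampling estimate of -log p(s) per sequence.

        Deterministic given ``seed``; computed in log space.  ``chunk`` caps
        how many sequences are expanded to (chunk, K, N*q) at once.
        """
        codes = self._validate(codes)
        n = len(codes)
        d = self.latent
        if chunk is None:
            chunk = max(1, int(2e7 // max(1, K * self.N)))
        out = np.empty(n)
        rng = np.random.default_rng(seed)
        for start in range(0, n, chunk):
            block = codes[start : start + chunk]
            m = len(block)
            mu, lv = self.encode(block)
            eps = rng.standard_normal((m, K, d))
            z = mu[:, None, :] + np.exp(0.5 * lv)[:, None, :] * eps
            z_flat = z.reshape(m * K, d)
            rep_codes = np.repeat(block, K, axis=0)
            log_pxz = self._decoder_logprob(z_flat, rep_codes).reshape(m, K)
            log_prior = -0.5 * np.sum(z**2, axis=2) - 0.5 * d * np.log(2 * np.pi)
            log_q = (
                -0.5 * np.sum(eps**2, axis=2)
                - 0.5 * np.sum(lv, axis=1)[:, None]
                - 0.5 * d * np.log(2 * np.pi)
            )
            out[start : start + m] = -(logsumexp(log_pxz + log_prior - log_q, axis=1) - np.log(K))
        return out

    def energy(self, codes: np.ndarray, seed: int = 0) -> np.ndarray:
        """Estimated energy -log p(s) via importance sampling with K=is_samples."""
        return self.energy_importance(codes, K=self.is_samples, seed=seed)

    def score_samples(self, X) -> np.ndarray:
        codes = X.codes if isinstance(X, EncodedAlignment) else np.atleast_2d(np.asarray(X))
        return -self.energy(codes)

    def score(self, X, y=None) -> float:
        return float(np.mean(self.score_samples(X)))


def train_vae(
    aln: EncodedAlignment,
    weights: np.ndarray | None = None,
    hidden: int = 40,
    latent: int = 5,
    weight_decay: float = 0.01,
    steps: int = 2000,
    lr: float = 0.01,
    seed: int = 0,
    **kwargs,
) -> SequenceVAE:
    """Functional wrapper over :class:`SequenceVAE.fit`."""
    model = SequenceVAE(
        hidden=hidden,
        latent=latent,
        weight_decay=weight_decay,
        steps=steps,
        lr=lr,
        seed=seed,
        **kwargs,
    )
    return model.fit(aln, sample_weight=weights)
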