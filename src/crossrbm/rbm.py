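"""Gauss-Bernoulli restricted Boltzmann machine: energies, conditionals,
free energy, score function, Gibbs transitions, and exact small-model oracles.

The model couples continuous visible units ``x`` in R^D to binary hidden
units ``h`` in {0,1}^H through the energy

    E(x, h) = 1/2 (x-c)^T L (x-c) - h^T W L x - b^T h,

where ``L = diag(lam)`` is the (learnable) diagonal precision of the visible
layer.  The induced conditionals are factorized:

    p(h | x) = Bernoulli( sigmoid(W L x + b) ),
    p(x | h) = Normal( W^T h + c,  L^{-1} ).

Marginalizing the hidden layer analytically gives the free energy

    F(x) = 1/2 (x-c)^T L (x-c) - sum_j softplus( (W L x + b)_j ),

so that p(x) is proportional to exp(-F(x)).  All functions accept a single
visible vector of shape ``(D,)`` or a batch of shape ``(n, D)`` and broadcast
accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .exceptions import CapabilityError, DimensionError, ValidationError

__all__ = [
    "RBMParams",
    "GibbsChain",
    "energy",
    "free_energy",
    "cond_hidden",
    "cond_visible",
    "sample_hidden",
    "sample_visible",
    "gibbs_sweep",
    "gibbs_run",
    "score_x",
    "exact_log_partition",
    "exact_visible_mixture",
    "sample_exact_visible",
]

# Exact enumeration over hidden configurations is O(2^H); beyond this the
# oracles refuse rather than silently thrash.
_ENUM_MAX_HIDDEN = 12


@dataclass
class RBMParams:
    """Parameters theta = {W, b, c, lam} of a Gauss-Bernoulli RBM.

    Attributes
    ----------
    W : (H, D) array
        Hidden-visible coupling weights.
    b : (H,) array
        Hidden biases.
    c : (D,) array
        Visible biases (the mean of the visible layer when W = 0).
    lam : (D,) array, strictly positive
        Diagonal of the visible precision matrix; the conditional visible
        covariance is diag(1/lam).
    """

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if self.W.ndim != 2 or self.b.ndim != 1 or self.c.ndim != 1 or self.lam.ndim != 1:
            raise DimensionError("W must be 2-D; b, c, lam must be 1-D")
        H, D = self.W.shape
        if self.b.shape != (H,) or self.c.shape != (D,) or self.lam.shape != (D,):
            raise DimensionError(
                f"inconsistent shapes: W {self.W.shape}, b {self.b.shape}, "
                f"c {self.c.shape}, lam {self.lam.shape}"
            )
        for name in ("W", "b", "c", "lam"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite entries in {name}")
        if np.any(self.lam <= 0):
            raise ValidationError("lam must be strictly positive")

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_visible(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.b.copy(), self.c.copy(), self.lam.copy())


@dataclass
class GibbsChain:
    """State of a visible-layer Markov chain (one h-then-x sweep per step)."""

    x: np.ndarray
    rng: np.random.Generator = field(repr=False)
    step_count: int = 0


def _softplus(z: np.ndarray) -> np.ndarray:
    # log(1 + e^z), overflow-safe for large |z|
    return np.logaddexp(0.0, z)


def _check_visible(x: np.ndarray, params: RBMParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.n_visible:
        raise DimensionError(
            f"visible dimension {x.shape[-1]} != model D={params.n_visible}"
        )
    return x

def _check_hidden(h: np.ndarray, params: RBMParams) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n_hidden:
        raise DimensionError(
            f"hidden dimension {h.shape[-1]} != model H={params.n_hidden}"
        )
    if not np.all((h == 0.0) | (h == 1.0)):
        raise ValidationError("h must be binary (entries in {0, 1})")
    return h


def hidden_field(x: np.ndarray, params: RBMParams) -> np.ndarray:
    """Pre-activation of the hidden layer, W L x + b."""
    x = _check_visible(x, params)
    return (x * params.lam) @ params.W.T + params.b


def energy(x: np.ndarray, h: np.ndarray, params: RBMParams) -> np.ndarray:
    """Joint energy E(x, h); scalar for vector inputs, vector for batches."""
    x = _check_visible(x, params)
    h = _check_hidden(h, params)
    d = x - params.c
    quad = 0.5 * np.sum(params.lam * d * d, axis=-1)
    inter = np.sum(h * ((x * params.lam) @ params.W.T), axis=-1)
    bias = h @ params.b
    return quad - inter - bias


def free_energy(x: np.ndarray, params: RBMParams) -> np.ndarray:
    """Free energy F(x) with the hidden layer summed out analytically."""
    x = _check_visible(x, params)
    d = x - params.c
    quad = 0.5 * np.sum(params.lam * d * d, axis=-1)
    return quad - np.sum(_softplus(hidden_field(x, params)), axis=-1)


def cond_hidden(x: np.ndarray, params: RBMParams) -> np.ndarray:
    """p(h_j = 1 | x) = sigmoid(W L x + b), elementwise."""
    return expit(hidden_field(x, params))


def cond_visible(h: np.ndarray, params: RBMParams):
    """Mean and diagonal precision of p(x | h) = N(W^T h + c, L^{-1})."""
    h = _check_hidden(h, params)
    return h @ params.W + params.c, params.lam


def sample_hidden(x: np.ndarray, params: RBMParams, rng: np.random.Generator) -> np.ndarray:
    p = cond_hidden(x, params)
    return (rng.random(p.shape) < p).astype(float)


def sample_visible(h: np.ndarray, params: RBMParams, rng: np.random.Generator) -> np.ndarray:
    mean, prec = cond_visible(h, params)
    return mean + rng.standard_normal(mean.shape) / np.sqrt(prec)


def gibbs_sweep(chain: GibbsChain, params: RBMParams) -> GibbsChain:
    """Advance the chain by one full h-then-x alternation (in place)."""
    h = sample_hidden(chain.x, params, chain.rng)
    chain.x = sample_visible(h, params, chain.rng)
    chain.step_count += 1
    return chain


def gibbs_run(
    x0: np.ndarray, k: int, params: RBMParams, rng: np.random.Generator
) -> np.ndarray:
    """Visible state after ``k`` full Gibbs sweeps started at ``x0``."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    chain = GibbsChain(x=_check_visible(x0, params).copy(), rng=rng)
    for _ in range(k):
        gibbs_sweep(chain, params)
    return chain.x


def score_x(x: np.ndarray, params: RBMParams) -> np.ndarray:
    """Score of the visible marginal, grad_x log p(x) = -grad_x F(x).

    Closed form: L (c - x) + L W^T sigmoid(W L x + b).
    """
    x = _check_visible(x, params)
    sig = cond_hidden(x, params)
    return params.lam * (params.c - x) + (sig @ params.W) * params.lam


def _enumerate_hidden(H: int) -> np.ndarray:
    if H > _ENUM_MAX_HIDDEN:
        raise CapabilityError(
            f"exact enumeration limited to H <= {_ENUM_MAX_HIDDEN}, got H={H}"
        )
    codes = np.arange(2**H)[:, None] >> np.arange(H)[None, :]
    return (codes & 1).astype(float)


def exact_visible_mixture(params: RBMParams):
    """Exact visible marginal as a 2^H-component Gaussian mixture (H <= 12).

    Returns ``(log_w, means, lam)``: normalized log mixture weights, the
    component means W^T h + c for every hidden configuration h, and the shared
    diagonal precision.  p(x) = sum_h w_h N(x; means_h, diag(1/lam)).
    """
    hs = _enumerate_hidden(params.n_hidden)
    means = hs @ params.W + params.c
    # unnormalized log weight of component h: b.h + (m_h^T L m_h - c^T L c)/2
    logw = hs @ params.b + 0.5 * (
        np.sum(params.lam * means * means, axis=1)
        - np.sum(params.lam * params.c * params.c)
    )
    from scipy.special import logsumexp

    logw = logw - logsumexp(logw)
    return logw, means, params.lam


def exact_log_partition(params: RBMParams) -> float:
    """log Z by exact hidden-layer enumeration (test oracle; H <= 12).

    For each hidden configuration the Gaussian integral over x is closed
    form, so log Z = logsumexp_h [ b.h + (m_h^T L m_h - c^T L c)/2 ]
    + D/2 log(2 pi) - 1/2 sum log lam.
    """
    from scipy.special import logsumexp

    hs = _enumerate_hidden(params.n_hidden)
    means = hs @ params.W + params.c
    logw = hs @ params.b + 0.5 * (
        np.sum(params.lam * means * means, axis=1)
        - np.sum(params.lam * params.c * params.c)
    )
    D = params.n_visible
    return float(
        logsumexp(logw) + 0.5 * D * np.log(2.0 * np.pi) - 0.5 * np.sum(np.log(params.lam))
    )


def sample_exact_visible(
    params: RBMParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact i.i.d. draws from the visible marginal via the enumerated mixture.

    Independent of the Gibbs sampler; used as a Monte-Carlo oracle in tests.
    """
    logw, means, lam = exact_visible_mixture(params)
    comp = rng.choice(len(logw), size=n, p=np.exp(logw))
    return means[comp] + rng.standard_normal((n, params.n_visible)) / np.sqrt(lam)
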