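"""Spike-train feature extraction.

Turns variable-length spike-timing trials into fixed-length per-subject
feature vectors: Gaussian-kernel smoothing of each muscle's spike train over
a fixed wing-stroke window, zero-fill of missing muscles, flattening across
the 10-muscle roster, and per-subject PCA down to P modes.

The smoothed trace for one muscle is x(t) = sum_n exp(-(t - t_n)^2 / (2 s^2))
evaluated on the grid t = 0, 1/fs, ..., (round(tau*fs)-1)/fs; spikes with
t_n > tau are discarded before summation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .exceptions import CapabilityError, ValidationError

__all__ = [
    "MUSCLE_ROSTER",
    "PCABasis",
    "FeatureDataset",
    "smooth_spikes",
    "assemble_trial",
    "assemble_table",
    "fit_pca",
    "apply_pca",
    "fit_zscore",
    "apply_zscore",
]

# Fixed roster: flight power muscles (DLM, DVM) and steering muscles
# (3AX, BA, SA) on the left and right side, in canonical order.
MUSCLE_ROSTER: tuple[str, ...] = (
    "L-DLM", "L-DVM", "L-3AX", "L-BA", "L-SA",
    "R-DLM", "R-DVM", "R-3AX", "R-BA", "R-SA",
)


@dataclass
class PCABasis:
    """Orthonormal PCA basis with deterministic component signs."""

    components: np.ndarray        # (raw_dim, P), columns orthonormal
    mean: np.ndarray              # (raw_dim,)
    explained_variance: np.ndarray  # (P,), non-increasing


@dataclass
class FeatureDataset:
    """Per-subject trial-by-feature matrix with stimulus labels."""

    subject_id: str
    X: np.ndarray                 # (n_trials, P)
    y: np.ndarray                 # (n_trials,) integer class labels
    pca: PCABasis | None = None
    raw_dim: int | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.y.shape != (self.X.shape[0],):
            raise ValidationError(
                f"X must be (n, P) with one label per row; got X {self.X.shape}, "
                f"y {self.y.shape}"
            )


def smooth_spikes(
    spike_times, tau: float = 60.0, sigma: float = 2.5, fs: float = 1.0
) -> np.ndarray:
    """Gaussian-kernel smoothing of one spike train onto a fixed time grid.

    Parameters
    ----------
    spike_times : sequence of float
        Spike timings in ms (ascending; unsorted input is sorted with a
        warning).
    tau : float
        Wing-stroke cut-off in ms; spikes with t_n > tau are excluded.
    sigma : float
        Kernel bandwidth in ms.
    fs : float
        Sampling frequency in kHz; the output has round(tau*fs) samples.
    """
    if tau <= 0 or sigma <= 0 or fs <= 0:
        raise ValidationError("tau, sigma and fs must be positive")
    t = np.asarray(spike_times, dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        warnings.warn("spike_times not sorted ascending; sorting", stacklevel=2)
        t = np.sort(t)
    n = int(round(tau * fs))
    grid = np.arange(n) / fs
    t = t[t <= tau]
    if t.size == 0:
        return np.zeros(n)
    return np.exp(-((grid[:, None] - t[None, :]) ** 2) / (2.0 * sigma**2)).sum(axis=1)


def assemble_trial(
    trial_rows: pd.DataFrame,
    missing: set[str] | frozenset[str] = frozenset(),
    tau: float = 60.0,
    sigma: float = 2.5,
    fs: float = 1.0,
) -> np.ndarray:
    """Smoothed, flattened feature vector for one trial across the roster.

    ``trial_rows`` holds one row per spike with columns ``muscle_id`` and
    ``spike_time_ms``; row order is irrelevant (roster order is canonical).
    Missing muscles contribute exact zero blocks.
    """
    unknown = set(trial_rows["muscle_id"]) - set(MUSCLE_ROSTER)
    if unknown:
        raise ValidationError(f"unknown muscle_id(s): {sorted(unknown)}")
    unknown_missing = set(missing) - set(MUSCLE_ROSTER)
    if unknown_missing:
        raise ValidationError(f"unknown muscle_id(s) in missing mask: {sorted(unknown_missing)}")
    n = int(round(tau * fs))
    blocks = []
    for muscle in MUSCLE_ROSTER:
        if muscle in missing:
            blocks.append(np.zeros(n))
        else:
            times = np.sort(trial_rows.loc[
                trial_rows["muscle_id"] == muscle, "spike_time_ms"
            ].to_numpy())
            blocks.append(smooth_spikes(times, tau=tau, sigma=sigma, fs=fs))
    return np.concatenate(blocks)


def assemble_table(
    spikes: pd.DataFrame,
    missing: dict[str, set[str]] | None = None,
    tau: float = 60.0,
    sigma: float = 2.5,
    fs: float = 1.0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Raw (pre-PCA) feature matrices for every subject in a spike table.

    ``spikes`` has columns subject_id, trial_id, label, muscle_id,
    spike_time_ms (one row per spike).  Returns
    ``{subject_id: (raw_matrix (n_trials, 10*round(tau*fs)), labels)}`` with
    trials ordered by trial_id.
    """
    missing = missing or {}
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for subject, sub in spikes.groupby("subject_id", sort=True):
        rows, labels = [], []
        for trial, tr in sub.groupby("trial_id", sort=True):
            lab = tr["label"].iloc[0]
            if tr["label"].nunique() > 1:
                raise ValidationError(
                    f"trial {trial!r} of subject {subject!r} has conflicting labels"
                )
            rows.append(
                assemble_trial(tr, missing.get(str(subject), set()), tau, sigma, fs)
            )
            labels.append(lab)
        out[str(subject)] = (np.vstack(rows), np.asarray(labels))
    return out


def fit_pca(train_matrix: np.ndarray, P: int) -> PCABasis:
    """PCA basis of the first P modes, fit on the TRAINING split only.

    Component signs are fixed so the largest-magnitude loading of each mode
    is positive, making the transform deterministic across SVD backends.
    """
    X = np.asarray(train_matrix, dtype=float)
    n, d = X.shape
    if P < 1:
        raise ValidationError("P must be >= 1")
    if P > min(n, d):
        raise CapabilityError(f"P={P} exceeds min(n_samples, raw_dim)={min(n, d)}")
    pca = PCA(n_components=P, svd_solver="full")
    pca.fit(X)
    if pca.explained_variance_[-1] <= 1e-12 * max(pca.explained_variance_[0], 1.0):
        raise CapabilityError(f"P={P} exceeds the effective rank of the training data")
    comps = pca.components_          # (P, d)
    flip = np.sign(comps[np.arange(P), np.argmax(np.abs(comps), axis=1)])
    comps = comps * flip[:, None]
    return PCABasis(
        components=comps.T,
        mean=pca.mean_,
        explained_variance=pca.explained_variance_.copy(),
    )


def apply_pca(matrix: np.ndarray, basis: PCABasis) -> np.ndarray:
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] != basis.components.shape[0]:
        raise ValidationError(
            f"matrix has {X.shape[1]} columns, basis expects {basis.components.shape[0]}"
        )
    return (X - basis.mean) @ basis.components


def fit_zscore(train_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension mean and standard deviation from the training split."""
    X = np.asarray(train_matrix, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return mu, np.where(sd > 1e-12, sd, 1.0)


def apply_zscore(matrix: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (np.asarray(matrix, dtype=float) - mu) / sd
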