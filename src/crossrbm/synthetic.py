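"""Synthetic multi-subject datasets with the statistical structure the
cross-subject mapping method assumes.

Two premises of the real recordings are emulated and asserted in tests:
(i) each subject's feature space is class-separable on its own, and (ii)
class geometry is misaligned across subjects, so a decoder trained on one
subject transfers at chance.  Feature-level data places shared latent class
means on a scaled regular simplex and pushes them through a subject-specific
map (random rotation, affine, or affine-plus-tanh warp) before adding
isotropic Gaussian noise.  Spike-level data emulates 10-muscle wing-stroke
trials: class- and muscle-specific template spike phases, per-trial jitter
and spike drop/add, a per-subject phase offset per muscle, and occasional
missing muscles (at most two per subject).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ortho_group

from .exceptions import ValidationError
from .features import MUSCLE_ROSTER, FeatureDataset

__all__ = ["SynthConfig", "gen_features", "gen_spikes"]


@dataclass
class SynthConfig:
    """Generator settings.

    The defaults emulate the study conditions this package targets: nine
    subjects, six stimulus classes, ~400 trials per class (≈2400 per
    subject), 10-dimensional feature spaces, and class separation of eight
    noise standard deviations so that within-subject linear decoding is
    near-perfect while cross-subject decoding without transfer is at chance.
    """

    n_subjects: int = 9
    n_classes: int = 6
    trials_per_class: int = 400
    latent_dim: int = 10
    feature_dim: int = 10
    class_separation: float = 4.0
    noise_sd: float = 0.5
    subject_map: str = "orthogonal"   # "orthogonal" | "affine" | "tanh_warp"
    missing_muscle_prob: float = 0.1
    seed: int = 0
    # spike-level settings (ms)
    tau: float = 60.0
    stroke_ms_range: tuple[float, float] = (50.0, 70.0)
    jitter_sd_ms: float = 1.0
    drop_prob: float = 0.05
    add_rate: float = 0.05
    subject_offset_sd_ms: float = 1.5

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_classes, self.trials_per_class,
               self.latent_dim, self.feature_dim) < 1:
            raise ValidationError("all counts must be positive")
        if self.noise_sd <= 0 or self.class_separation < 0:
            raise ValidationError("noise_sd must be > 0 and class_separation >= 0")
        if self.subject_map not in ("orthogonal", "affine", "tanh_warp"):
            raise ValidationError(f"unknown subject_map {self.subject_map!r}")
        if self.latent_dim < self.n_classes - 1:
            raise ValidationError("latent_dim must be >= n_classes - 1 for a simplex")
        if self.feature_dim != self.latent_dim:
            raise ValidationError("feature_dim must equal latent_dim for the built-in maps")


def _simplex_means(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Class means: vertices of a regular simplex (unit circumradius) scaled
    by class_separation and randomly rotated in latent space."""
    K, L = config.n_classes, config.latent_dim
    verts = np.eye(K) - 1.0 / K          # simplex vertices in a (K-1)-dim hyperplane
    _, _, vt = np.linalg.svd(verts)
    coords = verts @ vt[: K - 1].T       # (K, K-1), equal norms and pairwise distances
    coords = coords / np.linalg.norm(coords, axis=1, keepdims=True)
    means = np.zeros((K, L))
    means[:, : K - 1] = coords
    rot = ortho_group.rvs(L, random_state=rng)
    return config.class_separation * means @ rot


def _subject_maps(config: SynthConfig, rng: np.random.Generator):
    maps = []
    L = config.latent_dim
    for _ in range(config.n_subjects):
        R = ortho_group.rvs(L, random_state=rng)
        if config.subject_map == "orthogonal":
            maps.append(("orthogonal", R, None, None, None))
        else:
            scale = rng.uniform(0.5, 1.5, size=L)
            shift = rng.standard_normal(L)
            warp_dims = None
            if config.subject_map == "tanh_warp":
                warp_dims = rng.choice(L, size=max(1, L // 2), replace=False)
            maps.append((config.subject_map, R, scale, shift, warp_dims))
    return maps


def _apply_map(z: np.ndarray, spec) -> np.ndarray:
    kind, R, scale, shift, warp_dims = spec
    out = z @ R.T
    if kind in ("affine", "tanh_warp"):
        out = out * scale + shift
    if kind == "tanh_warp":
        out = out.copy()
        out[:, warp_dims] = np.tanh(out[:, warp_dims])
    return out


def gen_features(config: SynthConfig) -> tuple[dict[str, FeatureDataset], dict]:
    """Per-subject feature datasets plus the generating ground truth.

    Returns ``(datasets, truth)`` where ``truth`` holds the latent class
    means and per-subject map specs (for diagnostics; never used by the
    method under test).
    """
    rng = np.random.default_rng(config.seed)
    means = _simplex_means(config, rng)
    maps = _subject_maps(config, rng)
    labels = np.repeat(np.arange(1, config.n_classes + 1), config.trials_per_class)
    datasets: dict[str, FeatureDataset] = {}
    for m in range(config.n_subjects):
        z = means[labels - 1]
        x = _apply_map(z, maps[m])
        x = x + config.noise_sd * rng.standard_normal(x.shape)
        perm = rng.permutation(len(labels))
        datasets[f"S{m + 1}"] = FeatureDataset(
            subject_id=f"S{m + 1}", X=x[perm], y=labels[perm]
        )
    truth = {"class_means": means, "subject_maps": maps}
    return datasets, truth


def gen_spikes(config: SynthConfig) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Spike-level trials: one row per spike, plus the missing-muscle mask.

    Template spike phases are drawn per (class, muscle) so that the
    multi-muscle phase pattern differs between classes by several kernel
    bandwidths; trials jitter the template, drop/add spikes at a low rate,
    and apply a per-subject phase offset per muscle.  Missing muscles are
    masked independently per (subject, muscle) with ``missing_muscle_prob``,
    capped at two per subject.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_classes
    margin = 5.0
    lo, hi = margin, config.tau - margin
    slot = (hi - lo) / K
    # per-muscle random permutation of class -> phase slot, so the joint
    # pattern over 10 muscles separates classes even if one slot spacing is
    # modest relative to the kernel bandwidth
    templates: dict[tuple[int, str], np.ndarray] = {}
    for mu_i, muscle in enumerate(MUSCLE_ROSTER):
        perm = rng.permutation(K)
        for k in range(K):
            base = lo + (perm[k] + 0.5) * slot
            n_spk = rng.integers(1, 3)
            offs = np.linspace(-1.0, 1.0, n_spk) if n_spk > 1 else np.zeros(1)
            templates[(k + 1, muscle)] = base + offs
    missing: dict[str, set[str]] = {}
    records = []
    for m in range(config.n_subjects):
        subject = f"S{m + 1}"
        mask = [mu for mu in MUSCLE_ROSTER if rng.random() < config.missing_muscle_prob]
        missing[subject] = set(mask[:2])
        offsets = {mu: config.subject_offset_sd_ms * rng.standard_normal()
                   for mu in MUSCLE_ROSTER}
        trial_no = 0
        for k in range(1, K + 1):
            for _ in range(config.trials_per_class):
                trial_no += 1
                trial_id = f"T{trial_no:05d}"
                stroke = rng.uniform(*config.stroke_ms_range)
                for muscle in MUSCLE_ROSTER:
                    if muscle in missing[subject]:
                        continue
                    times = templates[(k, muscle)] + offsets[muscle]
                    keep = rng.random(times.size) >= config.drop_prob
                    times = times[keep]
                    times = times + config.jitter_sd_ms * rng.standard_normal(times.size)
                    n_add = rng.poisson(config.add_rate)
                    if n_add:
                        times = np.concatenate([times, rng.uniform(0, stroke, n_add)])
                    times = np.sort(times[(times >= 0) & (times < stroke)])
                    for t in times:
                        records.append((subject, trial_id, k, muscle, float(t)))
    df = pd.DataFrame(
        records,
        columns=["subject_id", "trial_id", "label", "muscle_id", "spike_time_ms"],
    )
    return df, missing
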