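"""Cross-subject mapping through a jointly trained Gauss-Bernoulli RBM.

The concatenated visible vector x = (x_1, ..., x_M) stacks one feature
vector per subject.  Training rows are built by random within-class pairing:
for every stimulus class, one trial per subject is drawn from that class and
the draws are concatenated, so each joint row is class-consistent across
subjects even though no trial-level correspondence exists.

At test time a target subject's features occupy their slice of the visible
vector, every other slice is initialized with standard-normal noise, and
k >= 1 Gibbs sweeps (sample h | x, then x | h) produce source-slice
representations that a source-trained decoder can classify.  With
``clamp="clamped"`` the target slices are re-imposed after every visible
update, which is the exact Gibbs sampler for p(x_S | x_T); with
``clamp="unclamped"`` the full visible vector is resampled each sweep.  At
k = 1 the two produce identical source outputs.  ``mode="mean_readout"``
replaces the final visible draw by the conditional mean W^T h + c on the
source slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import rbm
from .exceptions import ValidationError
from .features import FeatureDataset
from .rbm import RBMParams

__all__ = ["SubjectLayout", "build_joint_training_set", "cross_subject_map"]


@dataclass(frozen=True)
class SubjectLayout:
    """Ordered subject roster with slices into the concatenated visible vector
    and a disjoint target/source role assignment."""

    subjects: tuple[str, ...]
    dims: tuple[int, ...]
    target_set: frozenset[str] = frozenset()
    source_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.dims):
            raise ValidationError("subjects and dims must have equal length")
        if len(set(self.subjects)) != len(self.subjects):
            raise ValidationError("duplicate subject ids")
        if any(d < 1 for d in self.dims):
            raise ValidationError("all subject dimensions must be >= 1")
        roster = set(self.subjects)
        if not (self.target_set <= roster and self.source_set <= roster):
            raise ValidationError("target/source sets must be subsets of the roster")
        if self.target_set & self.source_set:
            raise ValidationError("target_set and source_set must be disjoint")

    @property
    def total_dim(self) -> int:
        return int(sum(self.dims))

    def slice_of(self, subject: str) -> slice:
        i = self.subjects.index(subject)
        start = int(sum(self.dims[:i]))
        return slice(start, start + self.dims[i])

    def indices_of(self, subject_set) -> np.ndarray:
        """Concatenated column indices of a subject set, in roster order."""
        idx = []
        for s in self.subjects:
            if s in subject_set:
                sl = self.slice_of(s)
                idx.extend(range(sl.start, sl.stop))
        return np.asarray(idx, dtype=int)

    def with_roles(self, target_set, source_set) -> "SubjectLayout":
        return SubjectLayout(
            self.subjects, self.dims, frozenset(target_set), frozenset(source_set)
        )

    @classmethod
    def from_datasets(cls, datasets: dict[str, FeatureDataset]) -> "SubjectLayout":
        subjects = tuple(sorted(datasets))
        dims = tuple(datasets[s].X.shape[1] for s in subjects)
        return cls(subjects, dims)


def build_joint_training_set(
    datasets: dict[str, FeatureDataset],
    layout: SubjectLayout,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated multi-subject training matrix via within-class pairing.

    For each class, N_k = max over subjects of that class's trial count; each
    subject contributes N_k trials of the class, drawn without replacement
    until its pool is exhausted and with replacement thereafter.  Returns the
    (sum_k N_k, D) matrix and its class labels.
    """
    classes = None
    for s in layout.subjects:
        if s not in datasets:
            raise ValidationError(f"no dataset for subject {s!r}")
        cls_s = set(np.unique(datasets[s].y).tolist())
        classes = cls_s if classes is None else classes | cls_s
    rows, labels = [], []
    for k in sorted(classes):
        pools = {}
        for s in layout.subjects:
            idx = np.flatnonzero(datasets[s].y == k)
            if idx.size == 0:
                raise ValidationError(f"subject {s!r} has no trials of class {k!r}")
            pools[s] = idx
        n_k = max(len(p) for p in pools.values())
        block = np.empty((n_k, layout.total_dim))
        for s in layout.subjects:
            pool = pools[s]
            picks = rng.permutation(pool)
            if n_k > len(pool):
                extra = rng.choice(pool, size=n_k - len(pool), replace=True)
                picks = np.concatenate([picks, extra])
            block[:, layout.slice_of(s)] = datasets[s].X[picks[:n_k]]
        rows.append(block)
        labels.extend([k] * n_k)
    return np.vstack(rows), np.asarray(labels)


def cross_subject_map(
    x_T: np.ndarray,
    layout: SubjectLayout,
    params: RBMParams,
    k: int = 1,
    mode: str = "mean_readout",
    clamp: str = "clamped",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Map target-subject features into the source-subject feature spaces.

    Parameters
    ----------
    x_T : (n, D_T) or (D_T,) array
        Target features, concatenated over ``layout.target_set`` in roster
        order.
    k : int
        Number of full Gibbs sweeps (>= 1).
    mode : {"mean_readout", "sampled"}
        Whether the final source readout is the conditional mean W^T h + c
        or a draw from p(x | h).
    clamp : {"clamped", "unclamped"}
        Whether target slices are re-imposed after every visible update.

    Returns
    -------
    (n, D_S) array of source-slice representations (target inputs are never
    mutated).
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if mode not in ("mean_readout", "sampled"):
        raise ValidationError(f"mode must be 'mean_readout' or 'sampled', got {mode!r}")
    if clamp not in ("clamped", "unclamped"):
        raise ValidationError(f"clamp must be 'clamped' or 'unclamped', got {clamp!r}")
    if not layout.target_set or not layout.source_set:
        raise ValidationError("layout must designate non-empty target and source sets")
    if params.n_visible != layout.total_dim:
        raise ValidationError(
            f"model D={params.n_visible} does not match layout D={layout.total_dim}"
        )
    rng = np.random.default_rng() if rng is None else rng
    t_idx = layout.indices_of(layout.target_set)
    s_idx = layout.indices_of(layout.source_set)
    x_T = np.atleast_2d(np.asarray(x_T, dtype=float))
    if x_T.shape[1] != t_idx.size:
        raise ValidationError(
            f"x_T has {x_T.shape[1]} columns, target slices total {t_idx.size}"
        )
    n = x_T.shape[0]
    xhat = np.empty((n, layout.total_dim))
    xhat[:, t_idx] = x_T
    noise_idx = np.setdiff1d(np.arange(layout.total_dim), t_idx)
    xhat[:, noise_idx] = rng.standard_normal((n, noise_idx.size))
    for step in range(k):
        h = rbm.sample_hidden(xhat, params, rng)
        if step == k - 1 and mode == "mean_readout":
            mean, _ = rbm.cond_visible(h, params)
            return mean[:, s_idx]
        xhat = rbm.sample_visible(h, params, rng)
        if clamp == "clamped":
            xhat[:, t_idx] = x_T
    return xhat[:, s_idx]
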