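"""Scenario I/II evaluation harness.

Scenario I fixes one subject as the source and maps every other subject's
test trials into its feature space; Scenario II fixes one subject as the
target and maps its test trials into every other subject's space, decoding
each with that subject's own decoder.  Methods compared per (source, target)
pair:

* ``subject_specific`` - decoder trained and tested on the same subject
  (upper-bound benchmark),
* ``no_transfer`` - source decoder applied to raw target features
  (chance-level lower bound),
* ``rbm_fd`` / ``rbm_cd`` - decode after Gibbs mapping through an RBM
  trained by score matching / contrastive divergence,
* ``external:<name>`` - any registered third-party alignment method
  (plug-in hook; nothing is registered by default).

Each repeat re-splits every subject's trials (stratified by class), z-scores
per subject on the training half, trains one RBM per method on the jointly
paired training set, and records micro-averaged 0/1 accuracy on the test
half.  Summaries report the mean over repeats with 2.5/97.5 percentile
confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import train_test_split

from . import crossmap, training
from .exceptions import ValidationError
from .features import FeatureDataset, apply_zscore, fit_zscore
from .training import TrainConfig

__all__ = [
    "EvalConfig",
    "EvalReport",
    "train_decoder",
    "run_scenario",
    "summarize",
    "register_aligner",
]

log = logging.getLogger(__name__)

# Registry for external alignment benchmarks (e.g. hierarchical Wasserstein
# alignment).  A factory returns an object with
# fit(source_X, source_y, target_X) -> self and transform(target_X) -> array.
_ALIGNERS: dict[str, object] = {}


def register_aligner(name: str, factory) -> None:
    _ALIGNERS[name] = factory


@dataclass
class EvalConfig:
    """Harness settings; defaults follow the target experimental protocol."""

    omega: float = 0.5            # train fraction of each subject's trials
    repeats: int = 100
    n_hidden: int = 15
    k: int = 1
    mode: str = "mean_readout"
    clamp: str = "clamped"
    zscore: bool = True
    methods: tuple[str, ...] = ("subject_specific", "no_transfer", "rbm_fd", "rbm_cd")
    fd_config: TrainConfig = field(default_factory=lambda: TrainConfig(method="fd"))
    cd_config: TrainConfig = field(default_factory=lambda: TrainConfig(method="cd"))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.omega < 1.0:
            raise ValidationError("omega must be in (0, 1)")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")


@dataclass
class EvalReport:
    """Accuracy samples for one (scenario, method, source, target) cell."""

    scenario: str
    method: str
    source_id: str
    target_id: str
    accuracies: np.ndarray

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValidationError("accuracies must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.accuracies, [2.5, 97.5])
        return float(lo), float(hi)


def train_decoder(X: np.ndarray, y: np.ndarray) -> LinearDiscriminantAnalysis:
    """Linear discriminant analysis decoder (shared within-class covariance).

    Falls back to a small logged ridge shrinkage if the pooled covariance is
    singular.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValidationError("decoder training requires >= 2 classes")
    clf = LinearDiscriminantAnalysis(solver="svd")
    try:
        with np.errstate(all="raise"):
            clf.fit(X, y)
    except (np.linalg.LinAlgError, FloatingPointError):
        eps = 1e-4
        log.warning("singular pooled covariance; refitting with ridge eps=%g", eps)
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=eps)
        clf.fit(X, y)
    return clf


def _split(
    ds: FeatureDataset, omega: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    Xtr, Xte, ytr, yte = train_test_split(
        ds.X, ds.y, train_size=omega, stratify=ds.y, random_state=seed
    )
    return Xtr, Xte, ytr, yte


def _accuracy(clf, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(clf.predict(X) == y))


def run_scenario(
    scenario: str,
    m: str,
    datasets: dict[str, FeatureDataset],
    config: EvalConfig,
) -> list[EvalReport]:
    """Evaluate all configured methods for pivot subject ``m``.

    In Scenario I, ``m`` is the single source and all other subjects are
    targets; in Scenario II, ``m`` is the single target and all other
    subjects are sources.  One RBM per training method is fit per repeat on
    the full roster's paired training set and reused for every pair.
    """
    if scenario not in ("I", "II"):
        raise ValidationError(f"scenario must be 'I' or 'II', got {scenario!r}")
    if m not in datasets:
        raise ValidationError(f"unknown pivot subject {m!r}")
    if len(datasets) < 2:
        raise ValidationError("need at least two subjects")
    subjects = sorted(datasets)
    others = [s for s in subjects if s != m]
    pairs = [(m, t) for t in others] if scenario == "I" else [(s, m) for s in others]
    rbm_methods = [meth for meth in config.methods
                   if meth in ("rbm_fd", "rbm_cd") or meth.startswith("external:")]
    acc: dict[tuple[str, str, str], list[float]] = {}
    ss = np.random.SeedSequence(config.seed)
    repeat_seeds = ss.generate_state(config.repeats)

    for r in range(config.repeats):
        seed_r = int(repeat_seeds[r] % (2**31 - 1))
        rng = np.random.default_rng(seed_r)
        splits = {s: _split(datasets[s], config.omega, seed_r) for s in subjects}
        if config.zscore:
            stats = {s: fit_zscore(splits[s][0]) for s in subjects}
            splits = {
                s: (
                    apply_zscore(splits[s][0], *stats[s]),
                    apply_zscore(splits[s][1], *stats[s]),
                    splits[s][2],
                    splits[s][3],
                )
                for s in subjects
            }
        decoders = {
            s: train_decoder(splits[s][0], splits[s][2]) for s in subjects
        }
        train_ds = {
            s: FeatureDataset(s, splits[s][0], splits[s][2]) for s in subjects
        }
        layout = crossmap.SubjectLayout.from_datasets(train_ds)
        models = {}
        if any(meth in ("rbm_fd", "rbm_cd") for meth in rbm_methods):
            Xjoint, _ = crossmap.build_joint_training_set(train_ds, layout, rng)
            for meth, tc in (("rbm_fd", config.fd_config), ("rbm_cd", config.cd_config)):
                if meth in config.methods:
                    tc_r = TrainConfig(**{
                        **tc.__dict__,
                        "seed": seed_r,
                        "batch_size": min(tc.batch_size, Xjoint.shape[0]),
                    })
                    models[meth], _ = training.train(
                        Xjoint, tc_r, n_hidden=config.n_hidden
                    )

        for source, target in pairs:
            if "subject_specific" in config.methods:
                key = ("subject_specific", source, target)
                acc.setdefault(key, []).append(
                    _accuracy(decoders[source], splits[source][1], splits[source][3])
                )
            Xte_t, yte_t = splits[target][1], splits[target][3]
            if "no_transfer" in config.methods:
                key = ("no_transfer", source, target)
                acc.setdefault(key, []).append(_accuracy(decoders[source], Xte_t, yte_t))
            for meth in rbm_methods:
                if meth.startswith("external:"):
                    name = meth.split(":", 1)[1]
                    if name not in _ALIGNERS:
                        raise ValidationError(f"no registered aligner {name!r}")
                    aligner = _ALIGNERS[name]().fit(
                        splits[source][0], splits[source][2], splits[target][0]
                    )
                    mapped = aligner.transform(Xte_t)
                else:
                    roles = layout.with_roles(
                        target_set={target},
                        source_set=set(subjects) - {target},
                    )
                    full = crossmap.cross_subject_map(
                        Xte_t, roles, models[meth], k=config.k,
                        mode=config.mode, clamp=config.clamp, rng=rng,
                    )
                    src_cols = roles.indices_of(roles.source_set)
                    want = roles.indices_of({source})
                    mapped = full[:, np.searchsorted(src_cols, want)]
                key = (meth, source, target)
                acc.setdefault(key, []).append(_accuracy(decoders[source], mapped, yte_t))
        log.info("scenario %s pivot %s repeat %d/%d done", scenario, m, r + 1, config.repeats)

    return [
        EvalReport(scenario, meth, src, tgt, np.asarray(v))
        for (meth, src, tgt), v in acc.items()
    ]


def summarize(reports: list[EvalReport]) -> pd.DataFrame:
    """Aggregate reports into a table of means and percentile CIs."""
    rows = []
    for rep in reports:
        lo, hi = rep.ci
        rows.append(
            {
                "scenario": rep.scenario,
                "method": rep.method,
                "source_id": rep.source_id,
                "target_id": rep.target_id,
                "n_repeats": len(rep.accuracies),
                "mean": rep.mean,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    cols = ["scenario", "method", "source_id", "target_id",
            "n_repeats", "mean", "ci_low", "ci_high"]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table = table.sort_values(cols[:4]).reset_index(drop=True)
    return table
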