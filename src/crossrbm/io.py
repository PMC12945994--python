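"""Readers and writers for the package's delimited-text schemas.

Every artifact file starts with a ``# schema: <name> v<major>`` header line;
readers reject files whose major version is newer than they understand.
Schemas are documented in docs/FORMATS.md.  Model checkpoints are JSON
key->array containers so they stay portable and inspectable.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .crossmap import SubjectLayout
from .exceptions import ValidationError
from .features import MUSCLE_ROSTER, FeatureDataset
from .rbm import RBMParams

__all__ = [
    "read_spike_table", "write_spike_table",
    "read_missing_roster", "write_missing_roster",
    "read_features", "write_features",
    "read_reports", "write_reports",
    "save_checkpoint", "load_checkpoint",
    "write_loss_trace",
]

_SCHEMA_VERSIONS = {
    "spike-table": 1,
    "muscle-roster": 1,
    "features": 1,
    "eval-report": 1,
    "loss-trace": 1,
}


def _write_header(fh, name: str, extra: dict | None = None) -> None:
    fh.write(f"# schema: {name} v{_SCHEMA_VERSIONS[name]}\n")
    for k, v in (extra or {}).items():
        fh.write(f"# {k}: {v}\n")


def _read_header(path: Path, name: str) -> tuple[dict, int]:
    """Validate the schema line; return header metadata and its line count."""
    meta: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        first = fh.readline().strip()
        n += 1
        if not first.startswith("# schema:"):
            raise ValidationError(f"{path}: missing '# schema:' header")
        try:
            got_name, ver = first.removeprefix("# schema:").strip().rsplit(" v", 1)
            major = int(ver)
        except ValueError as e:
            raise ValidationError(f"{path}: malformed schema header {first!r}") from e
        if got_name != name:
            raise ValidationError(f"{path}: expected schema {name!r}, found {got_name!r}")
        if major > _SCHEMA_VERSIONS[name]:
            raise ValidationError(
                f"{path}: schema {name} v{major} is newer than supported "
                f"v{_SCHEMA_VERSIONS[name]}"
            )
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta, n


_SPIKE_COLS = ["subject_id", "trial_id", "label", "muscle_id", "spike_time_ms"]


def write_spike_table(path, spikes: pd.DataFrame) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, "spike-table")
        spikes[_SPIKE_COLS].to_csv(fh, sep="\t", index=False)


def read_spike_table(path) -> pd.DataFrame:
    path = Path(path)
    _, n_header = _read_header(path, "spike-table")
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=n_header)
    unknown = set(df.columns) - set(_SPIKE_COLS)
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {sorted(unknown)}", stacklevel=2)
        df = df[[c for c in df.columns if c in _SPIKE_COLS]]
    missing_cols = set(_SPIKE_COLS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {sorted(missing_cols)}")
    bad = ~df["muscle_id"].isin(MUSCLE_ROSTER)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: out-of-roster muscle_id {df['muscle_id'].iloc[row]!r} "
            f"at data row {row + 1} (file line {row + 2 + n_header})"
        )
    if df["spike_time_ms"].isna().any() or (df["spike_time_ms"] < 0).any():
        row = int(np.flatnonzero((df["spike_time_ms"].isna()
                                  | (df["spike_time_ms"] < 0)).to_numpy())[0])
        raise ValidationError(f"{path}: invalid spike_time_ms at data row {row + 1}")
    return df


def write_missing_roster(path, missing: dict[str, set[str]]) -> None:
    with open(path, "w") as fh:
        _write_header(fh, "muscle-roster")
        fh.write("subject_id\tmuscle_id\n")
        for s in sorted(missing):
            for mu in sorted(missing[s]):
                fh.write(f"{s}\t{mu}\n")


def read_missing_roster(path) -> dict[str, set[str]]:
    path = Path(path)
    _, n_header = _read_header(path, "muscle-roster")
    df = pd.read_csv(path, sep="\t", skiprows=n_header)
    out: dict[str, set[str]] = {}
    for i, row in df.iterrows():
        if row["muscle_id"] not in MUSCLE_ROSTER:
            raise ValidationError(
                f"{path}: out-of-roster muscle {row['muscle_id']!r} at data row {i + 1}"
            )
        out.setdefault(str(row["subject_id"]), set()).add(row["muscle_id"])
    return out


def write_features(path, ds: FeatureDataset) -> None:
    with open(path, "w") as fh:
        _write_header(fh, "features", {"subject": ds.subject_id})
        cols = ["label"] + [f"f{i}" for i in range(ds.X.shape[1])]
        fh.write("\t".join(cols) + "\n")
        for lab, row in zip(ds.y, ds.X):
            fh.write(str(lab) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_features(path) -> FeatureDataset:
    path = Path(path)
    meta, n_header = _read_header(path, "features")
    df = pd.read_csv(path, sep="\t", skiprows=n_header)
    if "label" not in df.columns:
        raise ValidationError(f"{path}: missing 'label' column")
    X = df.drop(columns="label").to_numpy(dtype=float)
    n_nan = int(np.isnan(X).sum())
    if n_nan:
        raise ValidationError(f"{path}: {n_nan} NaN feature cell(s); file rejected")
    return FeatureDataset(
        subject_id=meta.get("subject", path.stem), X=X, y=df["label"].to_numpy()
    )


def write_reports(path, reports) -> None:
    """Persist EvalReports in long form (one row per repeat) for exact
    round-tripping of the per-repeat accuracies."""
    with open(path, "w") as fh:
        _write_header(fh, "eval-report")
        fh.write("scenario\tmethod\tsource_id\ttarget_id\trepeat\taccuracy\n")
        for rep in reports:
            for r, a in enumerate(rep.accuracies):
                fh.write(
                    f"{rep.scenario}\t{rep.method}\t{rep.source_id}\t"
                    f"{rep.target_id}\t{r}\t{a:.17g}\n"
                )


def read_reports(path):
    from .evaluation import EvalReport

    path = Path(path)
    _, n_header = _read_header(path, "eval-report")
    df = pd.read_csv(path, sep="\t", skiprows=n_header, float_precision="round_trip")
    out = []
    for (sc, meth, src, tgt), grp in df.groupby(
        ["scenario", "method", "source_id", "target_id"], sort=True
    ):
        grp = grp.sort_values("repeat")
        out.append(EvalReport(sc, meth, str(src), str(tgt), grp["accuracy"].to_numpy()))
    return out


def write_loss_trace(path, trace: list[dict]) -> None:
    with open(path, "w") as fh:
        _write_header(fh, "loss-trace")
        fh.write("epoch\tobjective\twall_time_s\n")
        for rec in trace:
            fh.write(f"{rec['epoch']}\t{rec['objective']:.10g}\t{rec['wall_time_s']:.6g}\n")


_CKPT_VERSION = 1


def save_checkpoint(
    path,
    params: RBMParams,
    layout: SubjectLayout | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Versioned JSON key->array model checkpoint."""
    doc = {
        "schema": "rbm-checkpoint",
        "version": _CKPT_VERSION,
        "arrays": {
            "W": params.W.tolist(),
            "b": params.b.tolist(),
            "c": params.c.tolist(),
            "lam": params.lam.tolist(),
        },
        "layout": None
        if layout is None
        else {"subjects": list(layout.subjects), "dims": list(layout.dims)},
        "config": config,
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_checkpoint(path) -> tuple[RBMParams, SubjectLayout | None, dict | None]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != "rbm-checkpoint":
        raise ValidationError(f"{path}: not an rbm-checkpoint file")
    if doc.get("version", 0) > _CKPT_VERSION:
        raise ValidationError(
            f"{path}: checkpoint version {doc['version']} newer than supported {_CKPT_VERSION}"
        )
    a = doc["arrays"]
    params = RBMParams(
        W=np.asarray(a["W"]), b=np.asarray(a["b"]),
        c=np.asarray(a["c"]), lam=np.asarray(a["lam"]),
    )
    layout = None
    if doc.get("layout"):
        layout = SubjectLayout(
            tuple(doc["layout"]["subjects"]), tuple(doc["layout"]["dims"])
        )
    return params, layout, doc.get("config")
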