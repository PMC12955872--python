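"""Readers/writers for per-pulse feature tables, sessions and configs.

The corpus schema is fixed: ``pulse_index, pressure_mpa, uh1..uh7, h2..h8,
broadband_db, mb_kinetics, x_mm, y_mm, tumor, label`` (extra columns such as
``subject_id`` are allowed and preserved).  Headers are required and missing
or non-finite values are rejected.  Every artifact written by the package
embeds provenance: the command/parameters, seed and package version.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import numpy as np
import yaml

from .subject import CORPUS_COLUMNS, SubjectModel

__all__ = [
    "read_corpus",
    "write_corpus",
    "read_subject_config",
    "write_subject_config",
    "write_session",
    "provenance",
    "SchemaError",
]

PACKAGE_VERSION = "0.1.0"


class SchemaError(ValueError):
    """A table does not conform to the corpus schema."""


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise SchemaError(f"missing values in column(s): {', '.join(bad)}")
    numeric = df[CORPUS_COLUMNS].apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any() or not np.all(np.isfinite(numeric.to_numpy())):
        raise SchemaError("non-finite or non-numeric values in corpus")
    return df


def read_corpus(path: str | Path) -> pd.DataFrame:
    """Read a per-pulse feature table (CSV or JSON by extension)."""
    path = Path(path)
    if path.suffix == ".json":
        blob = json.loads(path.read_text())
        df = pd.DataFrame(blob["rows"]) if isinstance(blob, dict) else pd.DataFrame(blob)
    else:
        df = pd.read_csv(path)
    return _validate(df)


def write_corpus(table: pd.DataFrame, path: str | Path,
                 meta: dict[str, Any] | None = None) -> None:
    """Write a corpus as CSV or JSON; validates the schema first.  JSON files
    carry provenance in-band; CSV provenance goes to a sidecar ``.meta.json``."""
    _validate(table)
    path = Path(path)
    if path.suffix == ".json":
        blob = {"provenance": provenance(meta), "rows": table.to_dict(orient="records")}
        path.write_text(json.dumps(blob))
    else:
        table.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(provenance(meta), indent=1))


def provenance(meta: dict[str, Any] | None = None) -> dict[str, Any]:
    out = {"package": "mbfus", "version": PACKAGE_VERSION}
    out.update(meta or {})
    return out


def read_subject_config(path: str | Path) -> SubjectModel:
    """Subject parameters from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SubjectModel.from_dict(data)


def write_subject_config(model: SubjectModel, path: str | Path) -> None:
    path = Path(path)
    data = model.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=1))
    else:
        path.write_text(yaml.safe_dump(data))


def write_session(session, path: str | Path, meta: dict[str, Any] | None = None) -> None:
    """Session log as CSV (one row per pulse) plus a JSON header sidecar."""
    path = Path(path)
    session.records.to_csv(path, index=False)
    header = provenance(meta)
    header.update({
        "seed": session.seed,
        "mode": session.config.mode,
        "target_level_db": session.config.target_level_db,
        "n_pulses": session.n_pulses,
        "events": session.event_count,
        "predictions": session.prediction_count,
        "dose_proxy": session.cumulative_dose,
    })
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(header, indent=1))
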