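"""Delimited-text readers/writers shared by all pipeline stages.

Everything is TSV: time-series files (T rows x N ROI columns, header of
roi ids), the subject manifest, square connectivity matrices with masked
cells serialised as ``NA``, and tidy metric tables. Round-trips preserve
float values to full precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import ConnectivityMatrix, TimeSeries

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_manifest",
    "read_manifest",
    "write_matrix",
    "read_matrix",
    "write_table",
    "read_table",
    "load_yaml_config",
]

MANIFEST_REQUIRED = ("subject_id", "path", "age", "scrub_percent")


class ManifestSchemaError(ValueError):
    """The manifest is missing required columns or has malformed rows."""


def write_timeseries(ts: TimeSeries, path) -> None:
    df = pd.DataFrame(ts.data, columns=[str(i) for i in ts.roi_ids])
    df.to_csv(path, sep="\t", index=False)


def read_timeseries(
    path,
    subject_id: str | None = None,
    tr_seconds: float = 2.0,
    scrub_fraction: float = 0.0,
) -> TimeSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"time-series file not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    try:
        roi_ids = np.array([int(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(
            f"{path}: header must be integer roi ids, got {list(df.columns)[:5]}"
        ) from exc
    return TimeSeries(
        subject_id=subject_id or path.stem,
        data=df.to_numpy(dtype=float),
        roi_ids=roi_ids,
        tr_seconds=tr_seconds,
        scrub_fraction=scrub_fraction,
    )


def write_manifest(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ManifestSchemaError(
            f"manifest {path} missing required column(s): {missing}"
        )
    bad = df.index[df["subject_id"].isna() | df["age"].isna()]
    if len(bad):
        # +2: header line plus 1-based indexing
        lines = [int(i) + 2 for i in bad]
        raise ManifestSchemaError(f"manifest {path}: malformed row(s) at line(s) {lines}")
    return df


def write_matrix(C: ConnectivityMatrix, path) -> None:
    """Square matrix with masked cells as literal ``NA``."""
    df = pd.DataFrame(
        C.with_nan(),
        index=C.node_ids,
        columns=[str(i) for i in C.node_ids],
    )
    df.to_csv(path, sep="\t", index_label="roi_id", na_rep="NA")


def read_matrix(path, subject_id: str = "") -> ConnectivityMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col="roi_id", na_values=["NA"],
                     float_precision="round_trip")
    z = df.to_numpy(dtype=float)
    mask = np.isnan(z)
    z = np.nan_to_num(z)
    return ConnectivityMatrix(
        z=z, mask=mask, node_ids=df.index.to_numpy(dtype=int),
        subject_id=subject_id or path.stem,
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def load_yaml_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    return loaded or {}
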