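"""ROI atlas handling: loading, network selection, and proximity exclusion.

The atlas is a table of spherical ROI centres in MNI millimetre space, each
carrying a functional-network label. Ten networks form the default analysis
selection; everything else is ``"unassigned"`` and dropped from analysis by
default. ROI pairs whose centres lie closer than a configurable distance
(default 20 mm) are excluded from all correlation-based computations.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "NETWORK_SIZES",
    "DEFAULT_NETWORKS",
    "RoiAtlas",
    "NetworkPartition",
    "AtlasFormatError",
    "AtlasValidationError",
    "load_atlas",
    "bundled_atlas_path",
    "load_bundled_atlas",
    "select_networks",
    "proximity_exclusion_pairs",
]

#: Canonical network vocabulary with the expected ROI count of the bundled
#: 264-ROI fixture (214 assigned + 50 unassigned).
NETWORK_SIZES: dict[str, int] = {
    "Hand": 30,
    "Vis": 31,
    "Mouth": 5,
    "Aud": 13,
    "DMN": 58,
    "Sal": 18,
    "CO": 14,
    "FP": 25,
    "DAN": 11,
    "VAN": 9,
}

DEFAULT_NETWORKS: tuple[str, ...] = tuple(NETWORK_SIZES)

UNASSIGNED = "unassigned"

_REQUIRED_COLUMNS = ("roi_id", "x", "y", "z", "network")


class AtlasFormatError(ValueError):
    """The atlas file is structurally malformed (missing columns, empty)."""


class AtlasValidationError(ValueError):
    """The atlas content violates an invariant (duplicate ids, bad label)."""


@dataclass(frozen=True)
class RoiAtlas:
    """An ordered table of ROI centres with network labels.

    Attributes
    ----------
    roi_ids : ndarray of int, shape (N,)
        Unique, contiguous 1..N identifiers, sorted ascending.
    xyz : ndarray of float, shape (N, 3)
        MNI centre coordinates in millimetres.
    networks : ndarray of str, shape (N,)
        Network label per ROI; ``"unassigned"`` for ROIs outside the
        analysis vocabulary.
    """

    roi_ids: np.ndarray
    xyz: np.ndarray
    networks: np.ndarray

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def labels_present(self) -> set[str]:
        return set(self.networks.tolist()) - {UNASSIGNED}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "network": self.networks,
            }
        )


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of a subset of ROIs to an ordered list of networks."""

    assignment: dict[int, str]
    selected_networks: tuple[str, ...]
    sizes: dict[str, int] = field(default_factory=dict)

    @property
    def roi_ids(self) -> np.ndarray:
        """ROI ids in the partition, ascending."""
        return np.array(sorted(self.assignment), dtype=int)

    @property
    def n_rois(self) -> int:
        return len(self.assignment)

    def network_of(self, roi_id: int) -> str:
        return self.assignment[roi_id]


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AtlasFormatError(f"atlas table is missing columns: {missing}")
    if len(df) == 0:
        raise AtlasFormatError("atlas table has no rows")

    ids = df["roi_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        dupes = sorted(pd.Series(ids)[pd.Series(ids).duplicated()].unique())
        raise AtlasValidationError(f"duplicate roi_id values: {dupes}")
    df = df.sort_values("roi_id").reset_index(drop=True)
    ids = df["roi_id"].to_numpy()
    if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
        raise AtlasValidationError("roi_id values must be contiguous 1..N")

    allowed = set(NETWORK_SIZES) | {UNASSIGNED}
    bad = sorted(set(df["network"]) - allowed)
    if bad:
        raise AtlasValidationError(f"unknown network labels: {bad}")
    return df


def load_atlas(path) -> RoiAtlas:
    """Read a delimited atlas table (TSV default, comma accepted).

    The file must have a header with columns ``roi_id x y z network``.
    Rows are normalised to ascending ``roi_id`` order.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise AtlasFormatError(f"empty or malformed atlas file: {path}") from exc
    df = _validate_frame(df)
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise AtlasValidationError("non-finite coordinate in atlas")
    return RoiAtlas(
        roi_ids=df["roi_id"].to_numpy(dtype=int),
        xyz=xyz,
        networks=df["network"].to_numpy(dtype=object),
    )


def bundled_atlas_path():
    """Path to the bundled 264-ROI / 10-network fixture atlas."""
    return importlib.resources.files("connseg") / "data" / "atlas264.tsv"


def load_bundled_atlas() -> RoiAtlas:
    return load_atlas(bundled_atlas_path())


def select_networks(
    atlas: RoiAtlas, names: list[str] | tuple[str, ...] | None = None
) -> NetworkPartition:
    """Restrict the atlas to the named networks (default: all ten).

    ROIs labelled ``"unassigned"`` or belonging to unselected networks are
    dropped from the partition and thereby from every downstream average
    and graph.
    """
    if names is None:
        names = DEFAULT_NETWORKS
    names = tuple(names)
    if not names:
        raise ValueError("network selection must be non-empty")
    unknown = [n for n in names if n not in NETWORK_SIZES]
    if unknown:
        raise ValueError(
            f"unknown network name(s) {unknown}; valid: {sorted(NETWORK_SIZES)}"
        )
    absent = [n for n in names if n not in atlas.labels_present()]
    if absent:
        raise ValueError(f"network(s) not present in atlas: {absent}")

    wanted = set(names)
    assignment: dict[int, str] = {}
    sizes = {n: 0 for n in names}
    for rid, net in zip(atlas.roi_ids.tolist(), atlas.networks.tolist()):
        if net in wanted:
            assignment[int(rid)] = net
            sizes[net] += 1
    return NetworkPartition(
        assignment=assignment, selected_networks=names, sizes=sizes
    )


def proximity_exclusion_pairs(
    atlas: RoiAtlas, threshold_mm: float = 20.0, strict: bool = True
) -> set[tuple[int, int]]:
    """Unordered ROI-id pairs whose centres lie within ``threshold_mm``.

    ``strict=True`` (default) uses ``d < threshold``, so boundary pairs at
    exactly the threshold distance are retained; ``strict=False`` uses
    ``d <= threshold``.
    """
    if not np.all(np.isfinite(atlas.xyz)):
        raise ValueError("non-finite coordinate in atlas")
    d = squareform(pdist(atlas.xyz))
    close = d < threshold_mm if strict else d <= threshold_mm
    iu, ju = np.triu_indices(atlas.n_rois, k=1)
    pairs: set[tuple[int, int]] = set()
    ids = atlas.roi_ids
    for i, j in zip(iu[close[iu, ju]], ju[close[iu, ju]]):
        a, b = int(ids[i]), int(ids[j])
        pairs.add((a, b) if a < b else (b, a))
    return pairs
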