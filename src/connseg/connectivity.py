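"""Subject-level connectivity: Pearson correlation, Fisher z, exclusion masks.

A subject's T x N ROI time-series matrix becomes an N x N Fisher-z
connectivity matrix carrying an explicit boolean exclusion mask (diagonal
plus geometrically proximate ROI pairs). Masked cells are flagged, never
sentinel-valued, so they cannot leak into averages; two accessors provide
the zero-filled view used for graph construction and the NaN view used for
correlation averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimeSeries",
    "ConnectivityMatrix",
    "correlation_matrix",
    "fisher_transform",
    "apply_masks",
    "subject_connectivity",
]

MIN_VOLUMES = 3


@dataclass
class TimeSeries:
    """BOLD amplitudes for one subject: T volumes by N ROIs."""

    subject_id: str
    data: np.ndarray
    roi_ids: np.ndarray
    tr_seconds: float = 2.0
    scrub_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D T x N array")
        if self.data.shape[0] < MIN_VOLUMES:
            raise ValueError(
                f"time series needs >= {MIN_VOLUMES} volumes, got {self.data.shape[0]}"
            )
        if self.data.shape[1] != len(self.roi_ids):
            raise ValueError("column count does not match roi_ids")
        if np.isnan(self.data).any():
            raise ValueError("time series contains missing values")
        if not 0.0 <= self.scrub_fraction < 1.0:
            raise ValueError("scrub_fraction must be in [0, 1)")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z matrix plus an explicit exclusion mask.

    ``mask[i, j] is True`` means the cell is excluded (self-correlation or
    proximity pair). ``z`` values under the mask are meaningless and must be
    read through :meth:`zero_filled` or :meth:`with_nan`.
    """

    z: np.ndarray
    mask: np.ndarray
    node_ids: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        n = len(self.node_ids)
        if self.z.shape != (n, n) or self.mask.shape != (n, n):
            raise ValueError("z and mask must be N x N matching node_ids")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def zero_filled(self) -> np.ndarray:
        """Copy with masked cells set to 0 (graph-construction view)."""
        out = self.z.copy()
        out[self.mask] = 0.0
        return out

    def with_nan(self) -> np.ndarray:
        """Copy with masked cells set to NaN (averaging view)."""
        out = self.z.copy()
        out[self.mask] = np.nan
        return out

    def restrict(self, node_ids) -> "ConnectivityMatrix":
        """Sub-matrix over the given node ids (order preserved ascending)."""
        wanted = np.asarray(sorted(node_ids), dtype=int)
        pos = {int(nid): k for k, nid in enumerate(self.node_ids)}
        missing = [int(n) for n in wanted if int(n) not in pos]
        if missing:
            raise ValueError(f"unknown node ids: {missing}")
        idx = np.array([pos[int(n)] for n in wanted])
        return ConnectivityMatrix(
            z=self.z[np.ix_(idx, idx)],
            mask=self.mask[np.ix_(idx, idx)],
            node_ids=wanted,
            subject_id=self.subject_id,
        )


def correlation_matrix(ts: TimeSeries) -> np.ndarray:
    """Pearson correlation among all ROI pairs of one subject.

    Raises ``ValueError`` naming the offending ROI if any column is
    constant (zero variance).
    """
    sd = ts.data.std(axis=0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        ids = ts.roi_ids[bad].tolist()
        raise ValueError(f"constant time series for ROI(s) {ids}")
    r = np.corrcoef(ts.data, rowvar=False)
    # clip numerical overshoot; exact +/-1 off-diagonal is caught downstream
    return np.clip(r, -1.0, 1.0)


def fisher_transform(r: np.ndarray) -> np.ndarray:
    """Elementwise arctanh. The diagonal (r = 1) maps to +inf and is
    expected to be masked afterwards; off-diagonal |r| = 1 is degenerate
    data and raises."""
    r = np.asarray(r, dtype=float)
    off = ~np.eye(r.shape[0], dtype=bool) if r.ndim == 2 and r.shape[0] == r.shape[1] else np.ones_like(r, dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        raise ValueError("off-diagonal correlation with |r| >= 1: degenerate data")
    with np.errstate(divide="ignore"):
        return np.arctanh(r)


def apply_masks(
    z: np.ndarray,
    pairs: set[tuple[int, int]],
    node_ids,
    subject_id: str = "",
) -> ConnectivityMatrix:
    """Attach the exclusion mask: full diagonal plus every proximity pair
    (symmetrised)."""
    node_ids = np.asarray(node_ids, dtype=int)
    n = len(node_ids)
    pos = {int(nid): k for k, nid in enumerate(node_ids)}
    mask = np.eye(n, dtype=bool)
    for a, b in pairs:
        if a not in pos or b not in pos:
            raise ValueError(f"proximity pair ({a}, {b}) references unknown node")
        i, j = pos[a], pos[b]
        mask[i, j] = mask[j, i] = True
    return ConnectivityMatrix(z=np.asarray(z, dtype=float), mask=mask,
                              node_ids=node_ids, subject_id=subject_id)


def subject_connectivity(
    ts: TimeSeries, pairs: set[tuple[int, int]] | None = None
) -> ConnectivityMatrix:
    """Convenience chain: correlation -> Fisher z -> masking."""
    r = correlation_matrix(ts)
    z = fisher_transform(r)
    return apply_masks(z, pairs or set(), ts.roi_ids, subject_id=ts.subject_id)
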