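"""Network-level correlation averages and the system-segregation statistic.

Two averaging conventions coexist deliberately:

* the per-network positive/negative means drop cells of the wrong sign
  entirely (they appear in neither numerator nor denominator);
* system segregation zeroes negative cells but keeps them in the cell
  counts (the ``"zeroed"`` variant, the default), with a ``"positives-only"``
  variant available.

Whole-brain within/between averages pool cells across all selected
networks (cell-weighted); a network-weighted variant (mean of network
means) is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import NetworkPartition
from .connectivity import ConnectivityMatrix

__all__ = [
    "SegregationResult",
    "network_positive_means",
    "network_negative_means",
    "network_correlation_summary",
    "system_segregation",
]


@dataclass(frozen=True)
class SegregationResult:
    ss: float
    zbar_within: float
    zbar_between: float


def _pair_masks(C: ConnectivityMatrix, P: NetworkPartition):
    """Boolean matrices flagging valid within-network and between-network
    cells (both orientations), restricted to partition nodes."""
    ids = C.node_ids
    known = set(int(i) for i in ids)
    missing = [i for i in P.assignment if i not in known]
    if missing:
        raise ValueError(f"partition nodes absent from matrix: {missing}")
    labels = np.array(
        [P.assignment.get(int(i), "") for i in ids], dtype=object
    )
    selected = np.array([lab != "" for lab in labels])
    same = labels[:, None] == labels[None, :]
    sel2 = selected[:, None] & selected[None, :]
    valid = ~C.mask
    within = valid & sel2 & same
    between = valid & sel2 & ~same
    return labels, within, between


def _mean_or_nan(vals: np.ndarray) -> tuple[float, int]:
    if vals.size == 0:
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)


def _directional_means(
    C: ConnectivityMatrix, P: NetworkPartition, sign: int
) -> pd.DataFrame:
    labels, within, between = _pair_masks(C, P)
    z = C.z
    keep = z > 0 if sign > 0 else z < 0
    rows = []
    tag = "pos" if sign > 0 else "neg"
    for net in P.selected_networks:
        in_net = labels == net
        w_mask = np.triu(within & keep, k=1) & in_net[:, None] & in_net[None, :]
        # between cells counted once per unordered pair; the row-wise scheme
        # means a cross cell contributes to both endpoint networks' means
        b_mask = between & keep & in_net[:, None]
        w_val, w_n = _mean_or_nan(z[w_mask])
        b_val, b_n = _mean_or_nan(z[np.triu(b_mask | b_mask.T, k=1)])
        rows.append(
            {"network": net, "metric": f"within_{tag}", "value": w_val,
             "n_cells": w_n, "analyzed": sign > 0}
        )
        rows.append(
            {"network": net, "metric": f"between_{tag}", "value": b_val,
             "n_cells": b_n, "analyzed": True}
        )
    return pd.DataFrame(rows)


def network_positive_means(
    C: ConnectivityMatrix, P: NetworkPartition
) -> pd.DataFrame:
    """Per-network mean of positive z values, within and between.

    Negative and masked cells are excluded from numerator and denominator.
    Undefined means (no qualifying cells) are reported as NaN with
    ``n_cells`` 0.
    """
    return _directional_means(C, P, sign=+1)


def network_negative_means(
    C: ConnectivityMatrix, P: NetworkPartition
) -> pd.DataFrame:
    """Mirror of :func:`network_positive_means` for negative z values.

    Within-network negative means are computed but flagged
    ``analyzed=False``: only the between-network negative means enter the
    group analyses.
    """
    return _directional_means(C, P, sign=-1)


def network_correlation_summary(
    C: ConnectivityMatrix, P: NetworkPartition
) -> pd.DataFrame:
    """Tidy long table of all per-network directional means."""
    return pd.concat(
        [network_positive_means(C, P), network_negative_means(C, P)],
        ignore_index=True,
    )


def _pooled_cells(C: ConnectivityMatrix, P: NetworkPartition):
    labels, within, between = _pair_masks(C, P)
    z = C.z
    w = z[np.triu(within, k=1)]
    b = z[np.triu(between, k=1)]
    return w, b


def system_segregation(
    C: ConnectivityMatrix,
    P: NetworkPartition,
    variant: str = "zeroed",
    network_weighted: bool = False,
) -> SegregationResult:
    """SS = (z_within - z_between) / z_within on positive-weight averages.

    ``variant="zeroed"`` (default): negative cells are set to 0 and kept in
    the averages. ``variant="positives-only"``: negative cells are dropped.
    ``network_weighted=True`` averages network means instead of pooling
    cells.
    """
    if variant not in ("zeroed", "positives-only"):
        raise ValueError(f"unknown SS variant: {variant!r}")

    if network_weighted:
        labels, within, between = _pair_masks(C, P)
        z = C.z
        w_means, b_means = [], []
        for net in P.selected_networks:
            in_net = labels == net
            wm = np.triu(within, k=1) & in_net[:, None] & in_net[None, :]
            bm = between & in_net[:, None]
            bm = np.triu(bm | bm.T, k=1)
            for cells, acc in ((z[wm], w_means), (z[bm], b_means)):
                if variant == "zeroed":
                    cells = np.maximum(cells, 0.0)
                else:
                    cells = cells[cells > 0]
                if cells.size:
                    acc.append(cells.mean())
        zw = float(np.mean(w_means)) if w_means else float("nan")
        zb = float(np.mean(b_means)) if b_means else float("nan")
    else:
        w, b = _pooled_cells(C, P)
        if variant == "zeroed":
            w, b = np.maximum(w, 0.0), np.maximum(b, 0.0)
        else:
            w, b = w[w > 0], b[b > 0]
        zw = float(w.mean()) if w.size else float("nan")
        zb = float(b.mean()) if b.size else float("nan")

    if not np.isfinite(zw) or zw <= 0:
        raise ValueError(
            f"system segregation undefined: mean within-network z = {zw}"
        )
    return SegregationResult(ss=(zw - zb) / zw, zbar_within=zw, zbar_between=zb)
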