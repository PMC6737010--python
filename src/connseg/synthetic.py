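"""Synthetic resting-state cohorts with block-structured covariance.

Each subject's ROI signals are multivariate-normal draws from a
correlation matrix with uniform within-network blocks (baseline +
linear age slope per network) and a uniform between-network / unassigned
level. Scrubbing is emulated by deleting a seeded random subset of
volumes, and cognition domain scores are coupled to the subject's
analytic (true-matrix) system segregation.

Temporal autocorrelation is deliberately not modelled: white-noise
volumes are sufficient for recovering correlation structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import NETWORK_SIZES, NetworkPartition, UNASSIGNED
from .connectivity import MIN_VOLUMES, TimeSeries
from .graphmetrics import round_half_away
from .groupstats import AGE_BINS, assign_age_group
from .netcorr import SegregationResult, system_segregation
from . import connectivity

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "build_covariance",
    "true_correlation",
    "true_segregation",
    "simulate_subject",
    "scrub_volumes",
    "simulate_cohort",
]

_SCAN_SHORT_T = 150
_SCAN_LONG_T = 285


def _as_network_dict(value, networks) -> dict[str, float]:
    if isinstance(value, dict):
        missing = [n for n in networks if n not in value]
        if missing:
            raise ValueError(f"missing per-network values for {missing}")
        return {n: float(value[n]) for n in networks}
    return {n: float(value) for n in networks}


@dataclass
class SimulationConfig:
    """Generative model for a synthetic aging cohort.

    Correlation levels are Pearson r at ``age_ref`` plus a linear
    per-year slope; within-network parameters may be scalars (shared) or
    per-network dicts.
    """

    network_sizes: dict[str, int] = field(
        default_factory=lambda: dict(NETWORK_SIZES)
    )
    n_unassigned: int = 50
    r_within_base: float | dict = 0.35
    r_within_slope: float | dict = -0.002
    r_between_base: float = 0.10
    r_between_slope: float = 0.0
    age_ref: float = 20.0
    noise_sd: float = 0.0
    t_volumes: int = _SCAN_LONG_T
    p_short: float = 0.0
    tr_seconds: float = 2.0
    n_per_group: int = 30
    age_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(AGE_BINS)
    )
    scrub_base: float = 0.02
    scrub_slope: float = 0.001
    scrub_sd: float = 0.01
    scrub_cutoff: float = 0.30
    cognition_beta: dict[str, float] = field(
        default_factory=lambda: {
            "VOCAB": 0.0, "SPEED": 2.0, "FLUID": 1.5, "MEM": 1.0,
        }
    )
    cognition_resid_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.r_within_base = _as_network_dict(
            self.r_within_base, self.network_sizes
        )
        self.r_within_slope = _as_network_dict(
            self.r_within_slope, self.network_sizes
        )
        if self.t_volumes < MIN_VOLUMES:
            raise ValueError("t_volumes too small")

    @property
    def labels(self) -> np.ndarray:
        out = [
            n for n, c in self.network_sizes.items() for _ in range(c)
        ] + [UNASSIGNED] * self.n_unassigned
        return np.array(out, dtype=object)

    @property
    def n_rois(self) -> int:
        return int(sum(self.network_sizes.values())) + self.n_unassigned

    @property
    def roi_ids(self) -> np.ndarray:
        return np.arange(1, self.n_rois + 1)

    def partition(self) -> NetworkPartition:
        assignment = {
            int(rid): lab
            for rid, lab in zip(self.roi_ids, self.labels)
            if lab != UNASSIGNED
        }
        names = tuple(self.network_sizes)
        return NetworkPartition(
            assignment=assignment,
            selected_networks=names,
            sizes=dict(self.network_sizes),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "age_ranges" in d:
            d["age_ranges"] = {
                k: tuple(v) for k, v in d["age_ranges"].items()
            }
        return cls(**d)


def _r_within(config: SimulationConfig, net: str, age: float) -> float:
    r = config.r_within_base[net] + config.r_within_slope[net] * (
        age - config.age_ref
    )
    return float(np.clip(r, 0.0, 0.95))


def _r_between(config: SimulationConfig, age: float) -> float:
    r = config.r_between_base + config.r_between_slope * (age - config.age_ref)
    return float(np.clip(r, 0.0, 0.95))


def true_correlation(config: SimulationConfig, age: float) -> np.ndarray:
    """The model's implied Pearson correlation matrix at a given age
    (after any white measurement noise)."""
    labels = config.labels
    n = len(labels)
    r = np.full((n, n), _r_between(config, age))
    start = 0
    for net, size in config.network_sizes.items():
        sl = slice(start, start + size)
        r[sl, sl] = _r_within(config, net, age)
        start += size
    np.fill_diagonal(r, 1.0)
    if config.noise_sd > 0:
        # additive white noise attenuates every off-diagonal correlation
        r = r / (1.0 + config.noise_sd**2)
        np.fill_diagonal(r, 1.0)
    return r


def build_covariance(
    config: SimulationConfig, age: float, max_repair: float = 0.05
) -> np.ndarray:
    """Unit-variance covariance (= correlation) matrix for one subject.

    Applies a nearest-PSD eigenvalue clip if the block construction is
    slightly indefinite; a required shift larger than ``max_repair``
    means the configuration is infeasible and raises.
    """
    cov = true_correlation(config, age)
    try:
        np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
        return cov
    except np.linalg.LinAlgError:
        pass
    vals, vecs = np.linalg.eigh(cov)
    shift = float(max(0.0, -vals.min()))
    if shift > max_repair:
        raise ValueError(
            f"infeasible correlation structure: PSD repair shift {shift:.4f} "
            f"exceeds {max_repair}"
        )
    logger.info("PSD repair applied, eigenvalue shift %.3g", shift)
    vals = np.clip(vals, 1e-10, None)
    cov = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def true_segregation(
    config: SimulationConfig, age: float, variant: str = "zeroed"
) -> SegregationResult:
    """System segregation of the noiseless model matrix at a given age."""
    r = true_correlation(config, age)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    C = connectivity.apply_masks(z, set(), config.roi_ids, subject_id="true")
    return system_segregation(C, config.partition(), variant=variant)


def simulate_subject(
    cov: np.ndarray,
    t_volumes: int,
    seed,
    subject_id: str = "sim",
    roi_ids=None,
    tr_seconds: float = 2.0,
) -> TimeSeries:
    """Draw ``t_volumes`` i.i.d. multivariate-normal volumes."""
    if t_volumes < MIN_VOLUMES:
        raise ValueError(f"need at least {MIN_VOLUMES} volumes")
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    data = rng.standard_normal((t_volumes, n)) @ chol.T
    if roi_ids is None:
        roi_ids = np.arange(1, n + 1)
    return TimeSeries(
        subject_id=subject_id, data=data, roi_ids=roi_ids,
        tr_seconds=tr_seconds,
    )


def scrub_volumes(ts: TimeSeries, fraction: float, seed) -> TimeSeries:
    """Delete ``round(fraction * T)`` volumes at seeded random positions."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("scrub fraction must be in [0, 1)")
    t = ts.n_volumes
    n_remove = round_half_away(fraction * t)
    if t - n_remove < MIN_VOLUMES:
        raise ValueError(
            f"scrubbing {n_remove}/{t} volumes leaves fewer than "
            f"{MIN_VOLUMES}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drop = rng.choice(t, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(t), drop)
    return TimeSeries(
        subject_id=ts.subject_id,
        data=ts.data[keep],
        roi_ids=ts.roi_ids,
        tr_seconds=ts.tr_seconds,
        scrub_fraction=n_remove / t,
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[TimeSeries], pd.DataFrame]:
    """Generate the full cohort: time series plus a subject-record table.

    Ages are uniform within each group's range; scrubbing grows with age
    plus half-normal noise; subjects at or above the scrub cutoff are
    excluded (and logged), mirroring the inclusion rule. Cognition domain
    scores are ``beta * true_SS + noise``, z-scored across the included
    cohort. Fully reproducible from ``config.seed``.
    """
    groups = list(config.age_ranges)
    total = config.n_per_group * len(groups)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(total)

    ts_list: list[TimeSeries] = []
    rows = []
    idx = 0
    for grp in groups:
        lo, hi = config.age_ranges[grp]
        for _ in range(config.n_per_group):
            rng = np.random.default_rng(children[idx])
            sid = f"sub-{idx + 1:04d}"
            idx += 1
            age = float(rng.uniform(lo, hi))
            frac = (
                config.scrub_base
                + config.scrub_slope * (age - config.age_ref)
                + abs(rng.normal(0.0, config.scrub_sd))
            )
            frac = float(max(frac, 0.0))
            t_vol = (
                _SCAN_SHORT_T
                if rng.uniform() < config.p_short
                else config.t_volumes
            )
            if frac >= config.scrub_cutoff:
                logger.warning(
                    "excluding %s: scrub fraction %.3f >= %.2f",
                    sid, frac, config.scrub_cutoff,
                )
                continue
            cov = build_covariance(config, age)
            ts = simulate_subject(
                cov, t_vol, rng, subject_id=sid,
                roi_ids=config.roi_ids, tr_seconds=config.tr_seconds,
            )
            ts = scrub_volumes(ts, frac, rng)
            ts_list.append(ts)
            seg = true_segregation(config, age)
            row = {
                "subject_id": sid,
                "age": age,
                "age_group": assign_age_group(age),
                "scrub_percent": 100.0 * ts.scrub_fraction,
                "scan_length": "long" if t_vol == _SCAN_LONG_T else "short",
                "n_volumes": ts.n_volumes,
                "true_ss": seg.ss,
            }
            rng_cog = np.random.default_rng(children[idx - 1].spawn(1)[0])
            for dom, beta in config.cognition_beta.items():
                row[f"raw_{dom}"] = beta * seg.ss + rng_cog.normal(
                    0.0, config.cognition_resid_sd
                )
            rows.append(row)

    records = pd.DataFrame(rows)
    for dom in config.cognition_beta:
        col = records[f"raw_{dom}"]
        sd = col.std(ddof=1)
        records[dom] = (col - col.mean()) / sd if sd > 0 else 0.0
    records = records.drop(
        columns=[f"raw_{d}" for d in config.cognition_beta]
    )
    return ts_list, records
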