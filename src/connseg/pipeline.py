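"""Stage orchestration: simulate -> connect -> metrics -> stats.

Each stage reads/writes delimited text under one output directory so runs
are diffable and resumable. All defaults mirror the analysis choices the
package is built around: 20-mm proximity exclusion, ten-network
selection, 2-10% density grid, scrubbing-percentage covariate, four age
bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .atlas import (
    DEFAULT_NETWORKS,
    RoiAtlas,
    load_atlas,
    load_bundled_atlas,
    proximity_exclusion_pairs,
    select_networks,
)
from .connectivity import subject_connectivity
from .graphmetrics import (
    DEFAULT_DENSITIES,
    global_efficiency,
    local_efficiency,
    modularity,
    network_average_nodal,
    participation_coefficient,
    proportional_threshold,
)
from .groupstats import (
    age_metric_correlation,
    ancova_effects,
    cognition_metric_correlations,
)
from .netcorr import network_correlation_summary, system_segregation
from .synthetic import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_simulate", "run_connect", "run_metrics",
           "run_stats", "run_all"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults match the analysis choices."""

    outdir: str = "connseg_out"
    atlas_path: str | None = None  # None -> bundled 264-ROI fixture
    networks: tuple[str, ...] = DEFAULT_NETWORKS
    proximity_mm: float = 20.0
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    mode: str = "weighted"
    ss_variant: str = "zeroed"
    covariate: bool = True
    scan_length_factor: bool = False
    gate_correlations: bool = False
    write_matrices: bool = False
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimulationConfig.from_dict(d["sim"])
        for key in ("densities", "networks"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def load_atlas(self) -> RoiAtlas:
        if self.atlas_path:
            return load_atlas(self.atlas_path)
        return load_bundled_atlas()


def _analysis_context(config: PipelineConfig):
    atlas = config.load_atlas()
    partition = select_networks(atlas, config.networks)
    pairs = proximity_exclusion_pairs(atlas, threshold_mm=config.proximity_mm)
    return atlas, partition, pairs


def run_simulate(config: PipelineConfig) -> pd.DataFrame:
    """Generate the synthetic cohort and write time series + manifest."""
    out = Path(config.outdir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    sim = config.sim
    ts_list, records = simulate_cohort(sim)
    paths = []
    for ts in ts_list:
        rel = f"timeseries/{ts.subject_id}.tsv"
        io.write_timeseries(ts, out / rel)
        paths.append(rel)
    records = records.copy()
    records.insert(1, "path", paths)
    io.write_manifest(records, out / "manifest.tsv")
    logger.info("simulated %d subjects -> %s", len(records), out)
    return records


def _iter_subjects(manifest: pd.DataFrame, base: Path):
    """Yield (manifest row, TimeSeries); relative paths resolve against
    the manifest's directory."""
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        ts = io.read_timeseries(
            p,
            subject_id=str(row["subject_id"]),
            scrub_fraction=float(row["scrub_percent"]) / 100.0,
        )
        yield row, ts


def run_connect(config: PipelineConfig, manifest: pd.DataFrame | None = None):
    """Connectivity matrices, network correlation means, segregation."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        manifest = io.read_manifest(out / "manifest.tsv")
    atlas, partition, pairs = _analysis_context(config)

    netcorr_rows, seg_rows = [], []
    if config.write_matrices:
        (out / "connectivity").mkdir(exist_ok=True)
    for row, ts in _iter_subjects(manifest, out):
        C = subject_connectivity(ts, pairs)
        Cp = C.restrict(partition.roi_ids)
        if config.write_matrices:
            io.write_matrix(C, out / "connectivity" / f"{ts.subject_id}.tsv")
        summ = network_correlation_summary(Cp, partition)
        summ.insert(0, "subject_id", ts.subject_id)
        netcorr_rows.append(summ)
        seg = system_segregation(Cp, partition, variant=config.ss_variant)
        seg_rows.append(
            {
                "subject_id": ts.subject_id,
                "ss": seg.ss,
                "zbar_within": seg.zbar_within,
                "zbar_between": seg.zbar_between,
            }
        )
    netcorr_long = pd.concat(netcorr_rows, ignore_index=True)
    seg_table = pd.DataFrame(seg_rows)
    io.write_table(netcorr_long, out / "netcorr.tsv")
    io.write_table(seg_table, out / "segregation.tsv")
    return netcorr_long, seg_table


def run_metrics(config: PipelineConfig, manifest: pd.DataFrame | None = None):
    """Thresholded graph metrics at every configured density."""
    out = Path(config.outdir)
    if manifest is None:
        manifest = io.read_manifest(out / "manifest.tsv")
    atlas, partition, pairs = _analysis_context(config)

    nodal_rows, global_rows, mean_rows = [], [], []
    for row, ts in _iter_subjects(manifest, out):
        C = subject_connectivity(ts, pairs).restrict(partition.roi_ids)
        for dens in config.densities:
            G = proportional_threshold(C, dens, mode=config.mode)
            pc = participation_coefficient(G, partition)
            le = local_efficiency(G)
            eglob = global_efficiency(G)
            mod = modularity(G, seed=config.seed)
            nodal_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": ts.subject_id,
                        "density": dens,
                        "mode": config.mode,
                        "node": G.node_ids,
                        "pc": pc,
                        "le": le,
                    }
                )
            )
            global_rows.append(
                {
                    "subject_id": ts.subject_id,
                    "density": dens,
                    "mode": config.mode,
                    "q": mod.modularity_q,
                    "eglob": eglob,
                }
            )
            for metric, vals in (("pc", pc), ("le", le)):
                means = network_average_nodal(vals, G, partition)
                for net, val in means.items():
                    mean_rows.append(
                        {
                            "subject_id": ts.subject_id,
                            "density": dens,
                            "network": net,
                            "metric": metric,
                            "value": val,
                        }
                    )
    nodal = pd.concat(nodal_rows, ignore_index=True)
    glob = pd.DataFrame(global_rows)
    means = pd.DataFrame(mean_rows)
    io.write_table(nodal, out / "graph_nodal.tsv")
    io.write_table(glob, out / "graph_global.tsv")
    io.write_table(means, out / "graph_network_means.tsv")
    return nodal, glob, means


def _effects_frame(effects, dv_name: str) -> pd.DataFrame:
    rows = []
    for e in effects:
        rows.append(
            {
                "dv": dv_name,
                "effect": e.effect,
                "F": e.f,
                "df1": e.df[0],
                "df2": e.df[1],
                "p": e.p,
            }
        )
    return pd.DataFrame(rows)


def run_stats(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Group tests, post hocs, age and cognition correlations."""
    out = Path(config.outdir)
    manifest = io.read_manifest(out / "manifest.tsv")
    netcorr_long = io.read_table(out / "netcorr.tsv")
    seg = io.read_table(out / "segregation.tsv")
    covariate = "scrub_percent" if config.covariate else None

    meta_cols = ["subject_id", "age", "age_group", "scrub_percent",
                 "scan_length"]
    meta = manifest[[c for c in meta_cols if c in manifest.columns]]

    effect_frames, posthoc_frames = [], []

    def record(effects, dv_name):
        effect_frames.append(_effects_frame(effects, dv_name))
        for e in effects:
            if e.posthoc is not None:
                ph = e.posthoc.copy()
                ph.insert(0, "dv", dv_name)
                ph.insert(1, "effect", e.effect)
                posthoc_frames.append(ph)

    # system segregation: one-way (ANCOVA with scrub covariate)
    seg_m = seg.merge(meta, on="subject_id")
    seg_eff = ancova_effects(
        seg_m, dv="ss", within=(), covariate=covariate
    )
    record(seg_eff, "ss")

    # positive correlations: group x direction x network
    pos = netcorr_long[
        netcorr_long["metric"].isin(["within_pos", "between_pos"])
    ].copy()
    pos["direction"] = pos["metric"].map(
        {"within_pos": "within", "between_pos": "between"}
    )
    pos_m = pos.merge(meta, on="subject_id")
    if pos_m["value"].notna().all():
        record(
            ancova_effects(
                pos_m, dv="value", within=("direction", "network"),
                covariate=covariate,
            ),
            "positive_correlation",
        )
    else:
        logger.warning("skipping positive-correlation ANCOVA: empty cells")

    # negative between-network correlations: group x network
    neg = netcorr_long[netcorr_long["metric"] == "between_neg"].copy()
    neg_m = neg.merge(meta, on="subject_id")
    if neg_m["value"].notna().all():
        record(
            ancova_effects(
                neg_m, dv="value", within=("network",), covariate=covariate
            ),
            "negative_correlation",
        )
    else:
        logger.warning("skipping negative-correlation ANCOVA: empty cells")

    # graph metrics if present
    metric_tables: dict[str, pd.DataFrame] = {}
    gm_path = out / "graph_network_means.tsv"
    gg_path = out / "graph_global.tsv"
    if gm_path.exists():
        means = io.read_table(gm_path)
        for metric in ("pc", "le"):
            sub = means[means["metric"] == metric].merge(meta, on="subject_id")
            record(
                ancova_effects(
                    sub, dv="value", within=("density", "network"),
                    covariate=covariate,
                ),
                metric,
            )
        metric_tables["graph_network_means"] = means
    if gg_path.exists():
        glob = io.read_table(gg_path)
        for metric in ("q", "eglob"):
            sub = glob.merge(meta, on="subject_id")
            record(
                ancova_effects(
                    sub, dv=metric, within=("density",), covariate=covariate
                ),
                metric,
            )
        metric_tables["graph_global"] = glob

    # optional scan-length between-subject factor
    if config.scan_length_factor and meta["scan_length"].nunique() > 1:
        record(
            ancova_effects(
                seg_m, dv="ss", between="scan_length", within=(),
                covariate=covariate,
            ),
            "ss_by_scan_length",
        )

    effects_table = pd.concat(effect_frames, ignore_index=True)
    posthoc_table = (
        pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames
        else pd.DataFrame()
    )

    # age correlations (optionally gated on the omnibus group effect)
    gate = {}
    if config.gate_correlations:
        for _, r in effects_table.iterrows():
            if r["effect"] == "age_group":
                gate[r["dv"]] = r["p"] < 0.05
    age_rows = []
    metric_long_rows = []

    def add_age_corr(dv_name, merged, value_col):
        if config.gate_correlations and not gate.get(dv_name, True):
            return
        r, p = age_metric_correlation(merged["age"], merged[value_col])
        age_rows.append({"metric": dv_name, "n": len(merged), "r": r, "p": p})

    add_age_corr("ss", seg_m, "ss")
    metric_long_rows.append(
        seg[["subject_id", "ss"]].rename(columns={"ss": "value"}).assign(
            metric="ss"
        )
    )
    for metric, grp in (
        ("within_pos", netcorr_long),
        ("between_pos", netcorr_long),
        ("between_neg", netcorr_long),
    ):
        sub = grp[grp["metric"] == metric]
        per_sub = sub.groupby("subject_id", as_index=False)["value"].mean()
        merged = per_sub.merge(meta, on="subject_id").dropna(subset=["value"])
        if len(merged) >= 3 and merged["value"].std() > 0:
            add_age_corr(metric, merged, "value")
        metric_long_rows.append(sub[["subject_id", "network", "value"]].assign(metric=metric))

    age_table = pd.DataFrame(age_rows)

    # cognition correlations over SS + per-network correlation metrics
    domains = tuple(
        d for d in ("VOCAB", "SPEED", "FLUID", "MEM") if d in manifest.columns
    )
    cog_table = pd.DataFrame()
    if domains:
        metric_long = pd.concat(metric_long_rows, ignore_index=True)
        cog_table = cognition_metric_correlations(
            manifest, metric_long, domains=domains
        )

    io.write_table(effects_table, out / "stats_effects.tsv")
    io.write_table(posthoc_table, out / "stats_posthoc.tsv")
    io.write_table(age_table, out / "stats_age_corr.tsv")
    io.write_table(cog_table, out / "stats_cognition_corr.tsv")
    return {
        "effects": effects_table,
        "posthoc": posthoc_table,
        "age_corr": age_table,
        "cognition_corr": cog_table,
    }


def run_all(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    manifest = run_simulate(config)
    run_connect(config, manifest=manifest)
    run_metrics(config, manifest=manifest)
    return run_stats(config)
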