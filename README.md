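# connseg

A resting-state functional-connectivity analysis pipeline: from per-subject
ROI time series to masked Fisher-z connectivity matrices, network-level
correlation averages, whole-brain system segregation, proportionally
thresholded graph metrics, and age-group / cognition statistics. A
synthetic-cohort generator with block-structured covariance makes the whole
chain testable end to end without any scan data.

## What it computes

- **atlas** — loads a 264-ROI atlas table (id, MNI x/y/z, network label),
  selects the ten analysis networks (Hand 30, Vis 31, Mouth 5, Aud 13,
  DMN 58, Sal 18, CO 14, FP 25, DAN 11, VAN 9; 214 ROIs total), and builds
  the < 20 mm centre-distance exclusion pair set. A bundled fixture atlas
  ships with the package (synthetic coordinates on a 22 mm grid, so its
  proximity set is empty by construction).
- **connectivity** — Pearson correlation across all ROI pairs, Fisher
  z-transform, and an explicit boolean exclusion mask (diagonal +
  proximity pairs). Masked cells are flags, not sentinels; a zero-filled
  view serves graph construction and a NaN view serves averaging.
- **netcorr** — per-network average positive within/between and negative
  between-network correlations (sign-dropped means), plus system
  segregation `SS = (z̄_within − z̄_between) / z̄_within` computed on
  pooled cells with negatives set to zero (a positives-only variant is
  available).
- **graphmetrics** — proportional thresholding (top `round(p·K)` positive
  unmasked edges, densities 2–10 % by 1 %), participation coefficient
  against the fixed atlas partition, local/global efficiency
  (weighted edge length = 1/weight), and seeded multi-restart Louvain
  modularity. Weighted and binary modes are both supported.
- **groupstats** — four inclusive age bins (YA 20–34, yMA 35–49, oMA
  50–64, OA 65–80), mixed between×within repeated-measures F tests with a
  scrubbing-percentage covariate in the between stratum, Bonferroni
  pairwise post hocs, and Pearson age/cognition correlations with
  whole-sample z-scored domain scores.
- **synthetic** — cohorts of multivariate-normal ROI time series whose
  within-network correlation declines linearly with age, scrubbing that
  grows with age (subjects at ≥ 30 % are excluded), and cognition scores
  coupled to each subject's analytic system segregation.

## CLI

```bash
connseg all --out results/run1 --seed 7          # simulate -> connect -> metrics -> stats
connseg simulate --out results/run1 --seed 7
connseg metrics --out results/run1 --densities 0.02,0.05 --mode binary
connseg stats --out results/run1
```

Options can also come from a YAML config (`--config cfg.yaml`) mirroring
the fields of `connseg.PipelineConfig` / `connseg.SimulationConfig`;
command-line flags override the file. Useful flags: `--networks`,
`--proximity-mm`, `--ss-variant {zeroed,positives-only}`,
`--scan-length-factor`. All outputs are TSV; connectivity matrices
serialise masked cells as `NA`.

## Library use

```python
import connseg as cs

cfg = cs.SimulationConfig(n_per_group=30, seed=1)
ts_list, records = cs.simulate_cohort(cfg)
part = cfg.partition()

C = cs.subject_connectivity(ts_list[0]).restrict(part.roi_ids)
seg = cs.system_segregation(C, part)
G = cs.proportional_threshold(C, 0.05, mode="weighted")
pc = cs.participation_coefficient(G, part)
```
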