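"""Group-level statistics: age bins, mixed ANCOVA, post hocs, correlations.

The factorial tests are univariate repeated-measures general-linear-model
F tests with subject error strata (a split-plot decomposition), an
approximation of the multivariate ANCOVAs common in SPSS workflows:

* between-subject effects (group, covariate) are tested on per-subject
  means with an OLS model comparison;
* each within-subject effect (and its interaction with group) is tested
  against the matching subject-by-effect interaction stratum;
* the covariate enters the between stratum only.

The within decomposition is exact for designs balanced across within
levels (required) and uses weighted-means sums of squares when group sizes
are unequal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AGE_GROUPS",
    "AGE_BINS",
    "GroupTestResult",
    "assign_age_group",
    "ancova_effects",
    "bonferroni_pairwise",
    "age_metric_correlation",
    "cognition_metric_correlations",
    "zscore_cognition",
]

AGE_GROUPS: tuple[str, ...] = ("YA", "yMA", "oMA", "OA")

#: inclusive age bins, in years
AGE_BINS: dict[str, tuple[int, int]] = {
    "YA": (20, 34),
    "yMA": (35, 49),
    "oMA": (50, 64),
    "OA": (65, 80),
}


def assign_age_group(age: float) -> str:
    """Map an age in years onto the four inclusive analysis bins."""
    for label, (lo, hi) in AGE_BINS.items():
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} outside the supported range [20, 80]")


@dataclass
class GroupTestResult:
    effect: str
    f: float
    df: tuple[float, float]
    p: float
    adjusted_means: dict[str, float] | None = None
    posthoc: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def _ssr(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _group_levels(series: pd.Series) -> list:
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [l for l in series.cat.categories if l in set(series)]
    uniq = pd.unique(series)
    known = [g for g in AGE_GROUPS if g in set(uniq)]
    if len(known) == len(uniq):
        return known
    return sorted(uniq)


def _center_axis(arr: np.ndarray, axis: int, weights=None) -> np.ndarray:
    if weights is None:
        return arr - arr.mean(axis=axis, keepdims=True)
    w = np.asarray(weights, dtype=float)
    shape = [1] * arr.ndim
    shape[axis] = len(w)
    w = w.reshape(shape)
    return arr - (arr * w).sum(axis=axis, keepdims=True) / w.sum()


def ancova_effects(
    data: pd.DataFrame,
    dv: str,
    subject: str = "subject_id",
    between: str = "age_group",
    within: tuple[str, ...] | list[str] = (),
    covariate: str | None = "scrub_percent",
    posthoc: bool = True,
) -> list[GroupTestResult]:
    """Mixed between x within F tests on a tidy long table.

    Parameters
    ----------
    data : long table, one row per subject per within-cell.
    dv : dependent-variable column.
    within : within-subject factor columns (every subject must have every
        level combination exactly once).
    covariate : subject-level covariate column, or None. A constant
        covariate is dropped with a warning.

    Returns one :class:`GroupTestResult` per effect: the between main
    effect, then each within subset and its interaction with the between
    factor.
    """
    within = tuple(within)
    cols = [subject, between, dv, *within]
    if covariate:
        cols.append(covariate)
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    df = data[cols].copy()

    levels = {w: sorted(pd.unique(df[w])) for w in within}
    glevels = _group_levels(df[between])

    # subject bookkeeping
    sub_info = df.groupby(subject).agg({between: "first"})
    if covariate:
        sub_info[covariate] = df.groupby(subject)[covariate].first()
    subjects = sub_info.index.to_numpy()
    n_sub = len(subjects)

    # balance check / reshape to (subject, l1, ..., lk)
    shape = [n_sub] + [len(levels[w]) for w in within]
    if within:
        piv = df.pivot_table(
            index=subject, columns=list(within), values=dv, aggfunc="mean",
            dropna=False,
        ).reindex(subjects)
        expected = int(np.prod(shape[1:]))
        if piv.shape[1] != expected or piv.isna().any().any():
            bad = piv.index[piv.isna().any(axis=1)].tolist()
            raise ValueError(
                f"unbalanced within-subject cells; offending subjects: {bad}"
            )
        Y = piv.to_numpy().reshape(shape)
    else:
        counts = df.groupby(subject)[dv].count()
        Y = df.groupby(subject)[dv].mean().reindex(subjects).to_numpy()
        if counts.max() != counts.min():
            raise ValueError("unequal replication per subject")
        Y = Y.reshape([n_sub])

    group_of = sub_info[between].to_numpy()
    g_idx = np.array([glevels.index(g) for g in group_of])
    n_g = np.array([(g_idx == k).sum() for k in range(len(glevels))])
    if (n_g == 0).any():
        raise ValueError("empty group level")

    x = None
    if covariate:
        x = sub_info[covariate].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(
                f"covariate {covariate!r} is constant; dropping it",
                stacklevel=2,
            )
            x = None

    results: list[GroupTestResult] = []

    # ---- between-subject stratum, on per-subject means ----------------
    m = Y.reshape(n_sub, -1).mean(axis=1)
    G = np.zeros((n_sub, len(glevels)))
    G[np.arange(n_sub), g_idx] = 1.0
    if x is not None:
        xc = (x - x.mean()).reshape(-1, 1)
        X_full = np.hstack([G, xc])
        X_red = np.hstack([np.ones((n_sub, 1)), xc])
        df_err = n_sub - len(glevels) - 1
    else:
        X_full = G
        X_red = np.ones((n_sub, 1))
        df_err = n_sub - len(glevels)
    df_eff = len(glevels) - 1
    if df_eff > 0:
        ssr_full = _ssr(X_full, m)
        ssr_red = _ssr(X_red, m)
        mse = ssr_full / df_err
        f_between = ((ssr_red - ssr_full) / df_eff) / mse if mse > 0 else 0.0
        f_between = max(f_between, 0.0)
        p_between = (
            float(stats.f.sf(f_between, df_eff, df_err)) if mse > 0 else 1.0
        )
        beta, *_ = np.linalg.lstsq(X_full, m, rcond=None)
        adj_means = {lvl: float(beta[k]) for k, lvl in enumerate(glevels)}
        ph = bonferroni_pairwise(m, group_of, order=glevels) if posthoc else None
        results.append(
            GroupTestResult(
                effect=between,
                f=float(f_between),
                df=(float(df_eff), float(df_err)),
                p=p_between,
                adjusted_means=adj_means,
                posthoc=ph,
            )
        )

    # ---- within strata ------------------------------------------------
    L_total = int(np.prod(shape[1:])) if within else 1
    for r in range(1, len(within) + 1):
        for combo in combinations(range(len(within)), r):
            w_names = [within[i] for i in combo]
            other = [i for i in range(len(within)) if i not in combo]
            # collapse over the within factors not in this subset
            Ysub = Y.mean(axis=tuple(a + 1 for a in other)) if other else Y
            l_s = int(np.prod([len(levels[w]) for w in w_names]))
            mult = L_total / l_s
            df_w = int(np.prod([len(levels[w]) - 1 for w in w_names]))

            # main within effect
            M = Ysub.mean(axis=0)
            E = M.copy()
            for ax in range(E.ndim):
                E = _center_axis(E, ax)
            ss_w = n_sub * mult * float((E**2).sum())

            # group x within interaction
            Mg = np.stack(
                [Ysub[g_idx == k].mean(axis=0) for k in range(len(glevels))]
            )
            Eg = _center_axis(Mg, 0, weights=n_g)
            for ax in range(1, Eg.ndim):
                Eg = _center_axis(Eg, ax)
            ss_gw = mult * float((n_g.reshape([-1] + [1] * (Eg.ndim - 1)) * Eg**2).sum())
            df_gw = (len(glevels) - 1) * df_w

            # error stratum: subject x within, within groups
            ss_err = 0.0
            for k in range(len(glevels)):
                T = Ysub[g_idx == k]
                R = T.copy()
                for ax in range(R.ndim):
                    R = _center_axis(R, ax)
                ss_err += mult * float((R**2).sum())
            df_err_w = int((n_g - 1).sum()) * df_w
            mse_w = ss_err / df_err_w if df_err_w > 0 else np.nan

            label = ":".join(w_names)
            for name, ss, dfe in (
                (label, ss_w, df_w),
                (f"{between}:{label}", ss_gw, df_gw),
            ):
                if dfe == 0:
                    continue
                f_val = (ss / dfe) / mse_w if mse_w > 0 else 0.0
                p_val = (
                    float(stats.f.sf(f_val, dfe, df_err_w))
                    if mse_w > 0
                    else 1.0
                )
                results.append(
                    GroupTestResult(
                        effect=name,
                        f=float(f_val),
                        df=(float(dfe), float(df_err_w)),
                        p=p_val,
                    )
                )
    return results


def bonferroni_pairwise(
    values,
    groups,
    order: list | None = None,
    m: int | None = None,
) -> pd.DataFrame:
    """All pairwise pooled-variance t tests with Bonferroni adjustment.

    ``p_adj = min(1, m * p_raw)`` where m defaults to the number of pairs
    (6 for four groups).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    lv = order if order is not None else sorted(pd.unique(groups))
    if len(lv) < 2:
        raise ValueError("need at least 2 groups for pairwise tests")
    by = {g: values[groups == g] for g in lv}
    for g, v in by.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    pairs = list(combinations(lv, 2))
    m_eff = m if m is not None else len(pairs)
    rows = []
    for a, b in pairs:
        va, vb = by[a], by[b]
        na, nb = len(va), len(vb)
        sp2 = ((na - 1) * va.var(ddof=1) + (nb - 1) * vb.var(ddof=1)) / (
            na + nb - 2
        )
        diff = va.mean() - vb.mean()
        if sp2 == 0:
            t, p_raw = 0.0, 1.0
        else:
            t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
            p_raw = float(2 * stats.t.sf(abs(t), na + nb - 2))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": float(diff),
                "t": float(t),
                "p_raw": p_raw,
                "p_adj": min(1.0, m_eff * p_raw),
            }
        )
    return pd.DataFrame(rows)


def age_metric_correlation(ages, values) -> tuple[float, float]:
    """Pearson r between age and a metric, two-sided p from the t
    transform."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) != len(values) or len(ages) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.std(ages) == 0 or np.std(values) == 0:
        raise ValueError("zero variance in age or metric")
    r, p = stats.pearsonr(ages, values)
    return float(r), float(p)


DOMAINS: tuple[str, ...] = ("VOCAB", "SPEED", "FLUID", "MEM")


def cognition_metric_correlations(
    records: pd.DataFrame,
    metrics: pd.DataFrame,
    domains: tuple[str, ...] = DOMAINS,
    subject: str = "subject_id",
) -> pd.DataFrame:
    """Pearson r between each cognitive-domain z-score and each metric.

    ``metrics`` is tidy long: subject_id, metric, optional network, value.
    No multiple-comparison correction is applied. Returns a long table
    (domain, metric, network, n, r, p).
    """
    keys = ["metric"] + (["network"] if "network" in metrics.columns else [])
    rows = []
    for key_vals, sub in metrics.groupby(keys, dropna=False):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        merged = sub.merge(records[[subject, *domains]], on=subject)
        for dom in domains:
            pair = merged[["value", dom]].dropna()
            if len(pair) < 3:
                continue
            r, p = age_metric_correlation(pair[dom], pair["value"])
            row = {"domain": dom, "metric": key_vals[0]}
            row["network"] = key_vals[1] if len(key_vals) > 1 else None
            row.update({"n": len(pair), "r": r, "p": p})
            rows.append(row)
    return pd.DataFrame(rows)


def zscore_cognition(
    raw: pd.DataFrame,
    domains: dict[str, list[str]],
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-task z-scoring against a reference sample, averaged into
    domain scores.

    Each task column is standardised by the reference sample's mean and
    SD (the raw table itself by default), then task z-scores are averaged
    without weighting within each domain.
    """
    ref = reference if reference is not None else raw
    zcols = {}
    for dom, tasks in domains.items():
        zs = []
        for task in tasks:
            mu, sd = ref[task].mean(), ref[task].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"zero-variance task {task!r} in reference")
            zs.append((raw[task] - mu) / sd)
        zcols[dom] = pd.concat(zs, axis=1).mean(axis=1)
    return pd.DataFrame(zcols, index=raw.index)
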