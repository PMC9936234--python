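"""Cohort-level inference: subtype contrasts, correlation panels, Cox models.

Three families of analysis link the per-sample repertoire measures
(expression/richness, entropy/diversity, and the network Gini indices) to
the cohort annotations:

* **Subtype contrasts** — two-sided Wilcoxon rank-sum (Mann–Whitney) tests
  for every unordered pair of molecular subtypes, per chain × measure, with
  the conventional star annotation (* p<0.05, ** p<0.01, *** p<0.001).
  The test is exact when both groups have ≤ 25 tie-free observations, and
  otherwise uses the normal approximation with tie and continuity
  correction.
* **Correlation panels** — tie-corrected Spearman correlations between each
  measure and the somatic mutation rates (non-silent NSMR, silent SMR) or
  the inflammatory score, for the pooled cohort ("All") and within each
  subtype.
* **Survival models** — Cox proportional-hazards fits (Efron tie handling)
  of overall survival on each measure, adjusted for age (continuous),
  geographic region (reference USA+Canada) and pathological stage
  (reference I-II), per stratum or, with ``interaction=True``, as a single
  model with measure × subtype product terms reporting per-subtype slopes.
  Richness enters on the log10 scale by default (zero-expression samples
  excluded rather than pseudo-counted); entropy enters in raw bits.

No multiple-testing correction is applied by default (per-pair stars are
reported as-is); Benjamini–Hochberg q-values are available behind a flag.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_clonotypes import REGIONS, STAGES, SUBTYPES

logger = logging.getLogger(__name__)

DEFAULT_MEASURES = ("expression", "entropy")
DEFAULT_COVARIATES = ("nsmr", "smr", "inflammatory_score")

#: Measures entered in Cox models on the log10 scale (zeros excluded).
LOG10_MEASURES = ("expression",)


def p_stars(p: float) -> str:
    """Conventional significance stars: * <0.05, ** <0.01, *** <0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    Returns the Mann–Whitney U statistic (of the first sample) and the
    two-sided p-value. Exact null distribution when both samples have ≤ 25
    observations with no cross-sample ties; otherwise the normal
    approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= 25 and len(y) <= 25 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _bh(frame: pd.DataFrame) -> pd.DataFrame:
    from statsmodels.stats.multitest import multipletests

    out = frame.copy()
    ok = out["p_value"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    out["q_value"] = q
    return out


def pairwise_wilcoxon(
    metrics: pd.DataFrame,
    metadata: pd.DataFrame,
    measures: Sequence[str] = DEFAULT_MEASURES,
    chains: Iterable[str] | None = None,
    bh: bool = False,
) -> pd.DataFrame:
    """Rank-sum contrasts of every unordered subtype pair, per chain × measure.

    ``metrics`` is a long table with ``sample_id``, ``chain`` and one column
    per measure; ``metadata`` supplies ``sample_id`` → ``subtype``. Missing
    measure values (e.g. undefined entropies) are excluded pairwise. Pairs
    in which either group has fewer than 2 non-missing values are skipped
    with a log entry.
    """
    merged = metrics.merge(metadata[["sample_id", "subtype"]], on="sample_id")
    if chains is None:
        chains = sorted(merged["chain"].unique())
    rows = []
    for chain in chains:
        sub = merged[merged["chain"] == chain]
        for measure in measures:
            groups = {
                s: sub.loc[sub["subtype"] == s, measure].dropna().to_numpy()
                for s in SUBTYPES
            }
            for a, b in itertools.combinations(SUBTYPES, 2):
                xa, xb = groups[a], groups[b]
                if len(xa) < 2 or len(xb) < 2:
                    logger.info(
                        "skipping %s/%s %s vs %s: group below 2 values", chain,
                        measure, a, b,
                    )
                    continue
                stat, p = rank_sum_test(xa, xb)
                rows.append(
                    dict(chain=chain, measure=measure, subtype_a=a, subtype_b=b,
                         n_a=len(xa), n_b=len(xb), statistic=stat, p_value=p,
                         stars=p_stars(p))
                )
    out = pd.DataFrame(rows)
    return _bh(out) if bh and len(out) else out


def correlation_panel(
    metrics: pd.DataFrame,
    metadata: pd.DataFrame,
    measures: Sequence[str] = DEFAULT_MEASURES,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    stratify_by_subtype: bool = True,
    bh: bool = False,
) -> pd.DataFrame:
    """Spearman correlations of measures with mutation rates / inflammatory score.

    One row per stratum ("All" plus each subtype when stratified) × chain ×
    measure × covariate, with tie-corrected rho and two-sided p. Fewer than
    3 complete pairs, or a constant vector, yields a missing rho.
    """
    cols = ["sample_id", "subtype"] + [c for c in covariates]
    merged = metrics.merge(metadata[cols], on="sample_id")
    strata = ["All"] + (list(SUBTYPES) if stratify_by_subtype else [])
    all_chains = sorted(merged["chain"].unique())
    rows = []
    for stratum in strata:
        part = merged if stratum == "All" else merged[merged["subtype"] == stratum]
        for chain in all_chains:
            sub = part[part["chain"] == chain]
            for measure in measures:
                for cov in covariates:
                    pair = sub[[measure, cov]].dropna()
                    rho = p = np.nan
                    n = len(pair)
                    if n >= 3 and pair[measure].nunique() > 1 and pair[cov].nunique() > 1:
                        res = sps.spearmanr(pair[measure], pair[cov])
                        rho, p = float(res.statistic), float(res.pvalue)
                    rows.append(
                        dict(subtype=stratum, chain=chain, measure=measure,
                             covariate=cov, rho=rho, p_value=p, n=n)
                    )
    out = pd.DataFrame(rows)
    return _bh(out) if bh and len(out) else out


def correlation_grid(panel: pd.DataFrame, covariate: str, measure: str) -> pd.DataFrame:
    """Pivot a correlation panel into the wide chain × stratum layout
    (cells hold "rho (p)") used for reporting."""
    sub = panel[(panel["covariate"] == covariate) & (panel["measure"] == measure)]
    cell = sub.apply(
        lambda r: f"{r.rho:.2f} ({r.p_value:.3g})" if np.isfinite(r.rho) else "NA",
        axis=1,
    )
    return (
        sub.assign(cell=cell)
        .pivot(index="chain", columns="subtype", values="cell")
        .reindex(columns=["All"] + list(SUBTYPES))
    )


def _design_frame(
    sub: pd.DataFrame, measure: str, log10_expression: bool
) -> pd.DataFrame:
    """Survival design matrix: transformed measure + age/region/stage dummies."""
    df = sub.copy()
    if log10_expression and measure in LOG10_MEASURES:
        df = df[df[measure] > 0]
        df["value"] = np.log10(df[measure])
    else:
        df["value"] = df[measure]
    df = df.dropna(subset=["value", "os_time", "os_event", "age_years"])
    df = df[df["os_time"] > 0]
    out = pd.DataFrame(
        {
            "os_time": df["os_time"].astype(float),
            "os_event": df["os_event"].astype(int),
            "value": df["value"].astype(float),
            "age_years": df["age_years"].astype(float),
        },
        index=df.index,
    )
    for r in REGIONS[1:]:
        out[f"region_{r}"] = (df["region"] == r).astype(float)
    for s in STAGES[1:]:
        out[f"stage_{s}"] = (df["stage"] == s).astype(float)
    out["subtype"] = df["subtype"].to_numpy()
    return out


def _fit_cox(design: pd.DataFrame, formula_cols: list[str]):
    from lifelines import CoxPHFitter

    cols = []
    for c in formula_cols:
        x = design[c]
        if x.nunique() <= 1:
            continue
        # indicator columns with a near-empty level are uninformative in
        # small strata and break the fit; drop them
        if set(x.unique()) <= {0.0, 1.0} and min(x.sum(), (1 - x).sum()) < 3:
            continue
        cols.append(c)
    cph = CoxPHFitter()
    cph.fit(
        design[["os_time", "os_event"] + cols],
        duration_col="os_time",
        event_col="os_event",
    )
    return cph


def cox_panel(
    metrics: pd.DataFrame,
    metadata: pd.DataFrame,
    measures: Sequence[str] = DEFAULT_MEASURES,
    stratify_by_subtype: bool = True,
    interaction: bool = False,
    min_samples: int = 10,
    min_events: int = 3,
    log10_expression: bool = True,
) -> pd.DataFrame:
    """Cox proportional-hazards panel for repertoire measures vs survival.

    Returns one row per stratum × chain × measure with the hazard ratio per
    unit of the (possibly log10-transformed) measure, its 95% CI, p-value,
    sample and event counts, and a convergence flag. Strata below the
    sample/event floors are skipped with a log entry. With
    ``interaction=True`` a single all-sample model with measure × subtype
    product terms is fitted per chain × measure and per-subtype slopes are
    reported (stratum column still carries the subtype).
    """
    meta_cols = ["sample_id", "subtype", "age_years", "region", "stage",
                 "os_time", "os_event"]
    merged = metrics.merge(metadata[meta_cols], on="sample_id")
    rows = []
    for chain in sorted(merged["chain"].unique()):
        sub = merged[merged["chain"] == chain]
        for measure in measures:
            design = _design_frame(sub, measure, log10_expression)
            if interaction:
                rows.extend(
                    _cox_interaction_rows(design, chain, measure, min_samples,
                                          min_events)
                )
                continue
            strata = ["All"] + (list(SUBTYPES) if stratify_by_subtype else [])
            for stratum in strata:
                part = design if stratum == "All" else design[design["subtype"] == stratum]
                n, events = len(part), int(part["os_event"].sum())
                if n < min_samples or events < min_events:
                    logger.info(
                        "skipping Cox %s/%s in %s: n=%d events=%d below floor",
                        chain, measure, stratum, n, events,
                    )
                    continue
                row = dict(subtype=stratum, chain=chain, measure=measure,
                           n=n, events=events)
                covs = ["value", "age_years"] + [
                    c for c in part.columns if c.startswith(("region_", "stage_"))
                ]
                try:
                    cph = _fit_cox(part, covs)
                    s = cph.summary.loc["value"]
                    row.update(
                        hazard_ratio=float(s["exp(coef)"]),
                        ci_low=float(s["exp(coef) lower 95%"]),
                        ci_high=float(s["exp(coef) upper 95%"]),
                        p_value=float(s["p"]),
                        converged=True,
                    )
                except Exception as exc:  # convergence failure is not fatal
                    logger.warning("Cox fit failed for %s/%s in %s: %s", chain,
                                   measure, stratum, exc)
                    row.update(hazard_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                               p_value=np.nan, converged=False)
                rows.append(row)
    return pd.DataFrame(rows)


def _cox_interaction_rows(
    design: pd.DataFrame, chain: str, measure: str, min_samples: int,
    min_events: int,
) -> list[dict]:
    """Single all-sample fit with measure × subtype terms; per-subtype slopes.

    The per-subtype log-HR is beta_value (+ beta_interaction for non-reference
    subtypes); its variance combines the two coefficients' covariance.
    """
    n, events = len(design), int(design["os_event"].sum())
    if n < min_samples or events < min_events:
        logger.info("skipping interaction Cox %s/%s: below floor", chain, measure)
        return []
    df = design.copy()
    present = [s for s in SUBTYPES if (df["subtype"] == s).any()]
    ref = present[0]
    inter_cols = []
    for s in present[1:]:
        ind = (df["subtype"] == s).astype(float)
        df[f"subtype_{s}"] = ind
        df[f"value_x_{s}"] = ind * df["value"]
        inter_cols.append(s)
    covs = (
        ["value", "age_years"]
        + [c for c in df.columns if c.startswith(("region_", "stage_"))]
        + [f"subtype_{s}" for s in inter_cols]
        + [f"value_x_{s}" for s in inter_cols]
    )
    try:
        cph = _fit_cox(df, covs)
    except Exception as exc:
        logger.warning("interaction Cox failed for %s/%s: %s", chain, measure, exc)
        return [dict(subtype="All", chain=chain, measure=measure, n=n, events=events,
                     hazard_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                     p_value=np.nan, converged=False)]

    params = cph.params_
    V = cph.variance_matrix_
    z = sps.norm.ppf(0.975)
    rows = []
    for s in present:
        beta = params["value"]
        var = V.loc["value", "value"]
        if s != ref and f"value_x_{s}" in params.index:
            key = f"value_x_{s}"
            beta = beta + params[key]
            var = var + V.loc[key, key] + 2.0 * V.loc["value", key]
        se = float(np.sqrt(var))
        part = design[design["subtype"] == s]
        rows.append(
            dict(subtype=s, chain=chain, measure=measure, n=len(part),
                 events=int(part["os_event"].sum()),
                 hazard_ratio=float(np.exp(beta)),
                 ci_low=float(np.exp(beta - z * se)),
                 ci_high=float(np.exp(beta + z * se)),
                 p_value=float(2 * sps.norm.sf(abs(beta / se))),
                 converged=True)
        )
    return rows
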