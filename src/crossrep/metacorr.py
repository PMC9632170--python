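"""Per-study correlation and Fisher-z fixed-effects meta-analysis.

Cross-receptor association is measured per study as Spearman's rank
correlation between paired B-cell and T-cell summary statistics across
individuals, then pooled across studies with a common-effect (fixed-effects)
inverse-variance meta-analysis on the Fisher z scale: z_k = atanh(r_k) with
variance 1/(n_k - 3).  Families of tests are corrected with Benjamini–
Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_STUDY_N = 4  # smallest per-study sample contributing to pooling


@dataclass
class MetaCorrelation:
    """Pooled correlation for one metric: per-study r/n plus Fisher-z summary."""

    metric: str
    study_ids: list[str] = field(default_factory=list)
    r_k: list[float] = field(default_factory=list)
    n_k: list[int] = field(default_factory=list)
    p_k: list[float] = field(default_factory=list)
    z: float = float("nan")
    se_z: float = float("nan")
    r: float = float("nan")
    ci95: tuple[float, float] = (float("nan"), float("nan"))
    p: float = float("nan")
    q: float = float("nan")


def spearman_rp(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties) with t-approximation p-value.

    Returns (nan, nan) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < MIN_STUDY_N:
        raise ValueError(f"need equal-length vectors with n >= {MIN_STUDY_N}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("spearman: constant vector, returning NA")
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def fisher_z_meta(r_list, n_list, study_ids=None, metric: str = "") -> MetaCorrelation:
    """Common-effect inverse-variance pooling of correlations on the z scale.

    z_k = atanh(r_k), var_k = 1/(n_k - 3); pooled z is the precision-weighted
    mean; pooled r = tanh(z); two-sided normal p; CI95 back-transformed.
    |r_k| = 1 is clipped to 0.999999 with a warning.
    """
    r = np.asarray(r_list, dtype=float)
    n = np.asarray(n_list, dtype=float)
    if len(r) == 0:
        raise ValueError("no studies to pool")
    if np.any(n < MIN_STUDY_N):
        raise ValueError(f"every study needs n >= {MIN_STUDY_N}")
    if np.any(np.abs(r) >= 1):
        logger.warning("|r|=1 clipped to 0.999999 before Fisher transform")
        r = np.clip(r, -0.999999, 0.999999)
    z_k = np.arctanh(r)
    w = n - 3.0  # 1/var_k
    z = float((w * z_k).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    p = float(2.0 * stats.norm.sf(abs(z) / se))
    res = MetaCorrelation(metric=metric)
    res.study_ids = list(study_ids) if study_ids is not None else [
        f"study{i}" for i in range(len(r))]
    res.r_k = [float(v) for v in r]
    res.n_k = [int(v) for v in n]
    res.z, res.se_z, res.r, res.p = z, se, float(np.tanh(z)), p
    res.ci95 = (float(np.tanh(z - 1.959963984540054 * se)),
                float(np.tanh(z + 1.959963984540054 * se)))
    return res


def bh_fdr(p_list) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_list, dtype=float)
    if len(p) == 0:
        return p
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def correlate_paired_metrics(
    stats_table: pd.DataFrame,
    condition: str,
    metrics: list[str],
    size: str | int = "full",
) -> list[MetaCorrelation]:
    """Meta-analyzed B–T Spearman correlation for each metric.

    ``stats_table`` is the long table from ``clonstats.summarize_cohort`` or
    ``repnet.network_summary_cohort`` (one row per individual × locus with
    metric columns).  For each metric: per-study Spearman r across paired
    individuals, Fisher-z pooling across studies, BH FDR across the metric
    family within this condition group.  Studies with fewer than four paired
    complete observations are excluded with a warning.
    """
    df = stats_table[stats_table["condition"] == condition]
    if "size" in df.columns:
        df = df[df["size"] == size]
    if "skipped" in df.columns:
        df = df[~df["skipped"].astype(bool)]
    results: list[MetaCorrelation] = []
    for metric in metrics:
        wide = df.pivot_table(index=["study_id", "individual_id"],
                              columns="locus", values=metric,
                              aggfunc="first").dropna()
        res = MetaCorrelation(metric=metric)
        for study, grp in wide.groupby(level="study_id"):
            if len(grp) < MIN_STUDY_N:
                logger.warning("%s: study %s has < %d paired individuals, excluded",
                               metric, study, MIN_STUDY_N)
                continue
            r, p = spearman_rp(grp["IGH"].values, grp["TRB"].values)
            if np.isnan(r):
                logger.warning("%s: study %s constant metric, dropped", metric, study)
                continue
            res.study_ids.append(study)
            res.r_k.append(r)
            res.n_k.append(len(grp))
            res.p_k.append(p)
        if res.r_k:
            pooled = fisher_z_meta(res.r_k, res.n_k, res.study_ids, metric=metric)
            pooled.p_k = res.p_k
            res = pooled
        results.append(res)
    qs = bh_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def meta_table(results: list[MetaCorrelation]) -> pd.DataFrame:
    """Flatten MetaCorrelation results into a forest-plot-style table."""
    rows = []
    for res in results:
        rows.append({
            "metric": res.metric,
            "k_studies": len(res.r_k),
            "per_study_r": ";".join(f"{s}:{r:.4f}(n={n})" for s, r, n
                                    in zip(res.study_ids, res.r_k, res.n_k)),
            "pooled_r": res.r, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
            "z": res.z, "se_z": res.se_z, "p": res.p, "q": res.q,
        })
    return pd.DataFrame(rows)


def covariate_adjusted_association(y, x, cov) -> tuple[float, float, float]:
    """OLS of y on [1, x, cov]; returns (slope on x, se, two-sided p).

    Used to test whether a cross-receptor association survives adjustment
    for sequencing quality (per-individual Q30 fraction).  Returns NaNs with
    a log flag when x and cov are collinear.
    """
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.asarray(x, dtype=float), np.asarray(cov, dtype=float)])
    if len(y) < 5:
        raise ValueError("need n >= 5")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        logger.warning("covariate collinear with predictor; returning NA")
        return float("nan"), float("nan"), float("nan")
    fit = sm.OLS(y, Xc).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
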