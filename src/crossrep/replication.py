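"""Replication of B×T cluster co-occurrence in an independent cohort.

For each cluster m and individual i, the *match fraction* Fr^m_i is the
fraction of the cluster's member clonotypes that the individual's
repertoire contains — exactly for T members, within a Levenshtein tolerance
(default 2) for B members, since exact matches of clustered B clonotypes
are rare.  If a cluster captures genuine B–T co-occurrence, Fr_T should
track Fr_B across individuals of a cohort that played no part in cluster
discovery.  This is tested with the pooled regression

    Fr_T ~ Fr_B + C,

where C is the individual's total repertoire size (unique B + T
clonotypes), with records iterating over all clusters and individuals; the
slope's significance is calibrated against refits on randomly drawn
clusters of the same sizes (empirical p with add-one correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .publiccluster import BTClusterPair
from .repdata import Cohort, Repertoire
from .repnet import levenshtein

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    """Observed Fr_T ~ Fr_B + C fit plus its random-cluster null."""

    slope: float
    se: float
    p: float
    n_records: int
    null_slopes: np.ndarray = field(default_factory=lambda: np.array([]))
    empirical_p: float = float("nan")


def cluster_match_fraction(rep: Repertoire, members, ld_tol: int = 0) -> float:
    """Fraction of cluster members present in the repertoire.

    A member counts (once) when the repertoire contains at least one
    clonotype within ``ld_tol`` edits of it; ``ld_tol=0`` is exact matching.
    """
    members = sorted(set(members))
    if not members:
        raise ValueError("empty member set")
    seqs = rep.sequences
    if ld_tol == 0:
        pool = set(seqs)
        hits = sum(m in pool for m in members)
        return hits / len(members)
    lens = np.array([len(s) for s in seqs])
    hits = 0
    for m in members:
        close = np.abs(lens - len(m)) <= ld_tol
        for s in np.array(seqs)[close]:
            if levenshtein(m, str(s), max_dist=ld_tol) <= ld_tol:
                hits += 1
                break
    return hits / len(members)


def match_matrix(cohort: Cohort, pool, locus: str, ld_tol: int) -> pd.DataFrame:
    """Individuals × pool-clonotype boolean match matrix.

    Entry (i, s) is True when individual i's repertoire of ``locus``
    contains a clonotype within ``ld_tol`` of pool member s.  Computing this
    once over the whole public pool lets observed clusters and the
    permutation null share the same precomputed fractions.
    """
    pool = sorted(set(pool))
    rows, index = [], []
    for rep in cohort.iter_repertoires(locus=locus):
        if not cohort.is_paired(rep.study_id, rep.individual_id):
            continue
        seqs = rep.sequences
        if ld_tol == 0:
            have = set(seqs)
            row = np.array([m in have for m in pool])
        else:
            lens = np.array([len(s) for s in seqs])
            arr = np.array(seqs)
            row = np.zeros(len(pool), dtype=bool)
            for j, m in enumerate(pool):
                for s in arr[np.abs(lens - len(m)) <= ld_tol]:
                    if levenshtein(m, str(s), max_dist=ld_tol) <= ld_tol:
                        row[j] = True
                        break
        rows.append(row)
        index.append((rep.study_id, rep.individual_id))
    return pd.DataFrame(rows, columns=pool,
                        index=pd.MultiIndex.from_tuples(
                            index, names=["study_id", "individual_id"]))


def _fraction_table_from_matrices(mat_b: pd.DataFrame, mat_t: pd.DataFrame,
                                  clusters, c_total: pd.Series) -> pd.DataFrame:
    common = mat_b.index.intersection(mat_t.index)
    Mb, Mt = mat_b.loc[common], mat_t.loc[common]
    col_b = {c: i for i, c in enumerate(Mb.columns)}
    col_t = {c: i for i, c in enumerate(Mt.columns)}
    n = len(common)
    frames = []
    for m, cl in enumerate(clusters):
        fr_b = Mb.values[:, [col_b[s] for s in cl.b_members]].mean(axis=1)
        fr_t = Mt.values[:, [col_t[s] for s in cl.t_members]].mean(axis=1)
        frames.append(pd.DataFrame({
            "study_id": common.get_level_values(0),
            "individual_id": common.get_level_values(1),
            "cluster_id": m, "fr_b": fr_b, "fr_t": fr_t,
            "c_total": c_total.loc[common].values}))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["study_id", "individual_id", "cluster_id",
                 "fr_b", "fr_t", "c_total"])


def repertoire_sizes(cohort: Cohort) -> pd.Series:
    """C_i: unique B + T clonotype count per paired individual."""
    data = {}
    for (study, indiv) in cohort.paired_individuals():
        c = sum(cohort.get(study, indiv, loc).clonal_volume
                for loc in ("IGH", "TRB"))
        data[(study, indiv)] = c
    s = pd.Series(data)
    s.index.names = ["study_id", "individual_id"]
    return s


def build_fraction_table(cohort: Cohort, clusters: list[BTClusterPair],
                         ld_tol_b: int = 2, ld_tol_t: int = 0) -> pd.DataFrame:
    """One (individual, cluster) record of Fr_B, Fr_T and C_i each."""
    pool_b = sorted({s for cl in clusters for s in cl.b_members})
    pool_t = sorted({s for cl in clusters for s in cl.t_members})
    mat_b = match_matrix(cohort, pool_b, "IGH", ld_tol_b)
    mat_t = match_matrix(cohort, pool_t, "TRB", ld_tol_t)
    return _fraction_table_from_matrices(mat_b, mat_t, clusters,
                                         repertoire_sizes(cohort))


def fit_fraction_regression(table: pd.DataFrame) -> RegressionResult:
    """OLS of fr_t on [1, fr_b, c_total]; slope on fr_b with t-test p."""
    if len(table) < 10:
        raise ValueError("need >= 10 records")
    if table["fr_b"].nunique() == 1:
        logger.warning("fr_b constant; slope undefined")
        return RegressionResult(float("nan"), float("nan"), float("nan"),
                                len(table))
    X = sm.add_constant(table[["fr_b", "c_total"]].astype(float).values)
    fit = sm.OLS(table["fr_t"].astype(float).values, X).fit()
    return RegressionResult(slope=float(fit.params[1]), se=float(fit.bse[1]),
                            p=float(fit.pvalues[1]), n_records=len(table))


def permutation_null(cohort: Cohort, clusters: list[BTClusterPair],
                     public_b, public_t, observed: RegressionResult | None = None,
                     n_iter: int = 100, ld_tol_b: int = 2, ld_tol_t: int = 0,
                     rng: np.random.Generator | None = None) -> RegressionResult:
    """Random-cluster null for the replication regression.

    Draws ``n_iter`` sets of random B and T clonotype clusters matching the
    observed cluster sizes from the public pools, refits the regression on
    each, and reports the null slope distribution plus the add-one empirical
    p-value (1 + #{|slope_null| >= |slope_obs|}) / (n_iter + 1).
    """
    rng = rng or np.random.default_rng()
    public_b, public_t = sorted(set(public_b)), sorted(set(public_t))
    for cl in clusters:
        if cl.n_b > len(public_b) or cl.n_t > len(public_t):
            raise ValueError("public pool smaller than a cluster")
    mat_b = match_matrix(cohort, public_b, "IGH", ld_tol_b)
    mat_t = match_matrix(cohort, public_t, "TRB", ld_tol_t)
    c_total = repertoire_sizes(cohort)

    if observed is None:
        obs_tab = _fraction_table_from_matrices(
            mat_b[[s for cl in clusters for s in cl.b_members]],
            mat_t[[s for cl in clusters for s in cl.t_members]],
            clusters, c_total)
        observed = fit_fraction_regression(obs_tab)

    null_slopes = np.empty(n_iter)
    arr_b, arr_t = np.array(public_b, dtype=object), np.array(public_t, dtype=object)
    for it in range(n_iter):
        rand_clusters = []
        for m, cl in enumerate(clusters):
            bm = list(arr_b[rng.choice(len(arr_b), size=cl.n_b, replace=False)])
            tm = list(arr_t[rng.choice(len(arr_t), size=cl.n_t, replace=False)])
            rand_clusters.append(BTClusterPair(m, bm, tm, float("nan")))
        tab = _fraction_table_from_matrices(mat_b, mat_t, rand_clusters, c_total)
        null_slopes[it] = fit_fraction_regression(tab).slope
    finite = null_slopes[np.isfinite(null_slopes)]
    emp_p = (1.0 + np.sum(np.abs(finite) >= abs(observed.slope))) / (len(finite) + 1.0)
    return RegressionResult(slope=observed.slope, se=observed.se, p=observed.p,
                            n_records=observed.n_records,
                            null_slopes=null_slopes, empirical_p=float(emp_p))
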