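"""Public clonotypes, B×T proportion correlations, and correlation clustering.

A *public* clonotype is a CDR3 amino-acid sequence found in two or more
individuals of a condition group (pooled across studies).  For each public
B (IGH) and T (TRB) clonotype, its clonal proportion within each
individual's whole B or T clonal space forms a column of a proportion
matrix (absent = exact 0).  Correlating every B column with every T column
per study and pooling via Fisher-z meta-analysis yields a B×T correlation
matrix; hierarchical clustering of its rows and columns exposes blocks of
mutually correlated B and T clonotypes, which are extracted as
``BTClusterPair`` objects by an explicit block-scoring criterion.

A separate cell-subset analysis correlates the proportions of the top-k
most frequent public clonotypes of each annotated cell subset and counts
highly correlated pairs per subset-pair category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .repdata import Cohort

logger = logging.getLogger(__name__)


@dataclass
class BTClusterPair:
    """A matched block of public B and T clonotypes with correlated proportions."""

    cluster_id: int
    b_members: list[str]
    t_members: list[str]
    mean_abs_r: float
    condition: str = ""

    @property
    def n_b(self) -> int:
        return len(self.b_members)

    @property
    def n_t(self) -> int:
        return len(self.t_members)


def find_public_clonotypes(cohort: Cohort, locus: str, condition: str,
                           min_individuals: int = 2) -> set[str]:
    """Clonotypes present in >= min_individuals of the condition group."""
    seen: dict[str, int] = {}
    for rep in cohort.iter_repertoires(locus=locus, condition=condition):
        for seq in rep.sequences:
            seen[seq] = seen.get(seq, 0) + 1
    return {seq for seq, n in seen.items() if n >= min_individuals}


def proportion_matrix(cohort: Cohort, clonotypes, locus: str,
                      condition: str) -> pd.DataFrame:
    """Individuals × clonotypes matrix of clonal proportions (absent = 0).

    Proportions are relative to the individual's full repertoire of the
    locus.  Rows are indexed by (study_id, individual_id); only individuals
    paired for both loci are included.
    """
    cols = sorted(clonotypes)
    col_idx = {c: i for i, c in enumerate(cols)}
    rows, index = [], []
    for rep in cohort.iter_repertoires(locus=locus, condition=condition):
        if not cohort.is_paired(rep.study_id, rep.individual_id):
            continue
        row = np.zeros(len(cols))
        for rec, p in zip(rep.records, rep.proportions):
            i = col_idx.get(rec.junction_aa)
            if i is not None:
                row[i] = p
        rows.append(row)
        index.append((rep.study_id, rep.individual_id))
    return pd.DataFrame(rows, columns=cols,
                        index=pd.MultiIndex.from_tuples(
                            index, names=["study_id", "individual_id"]))


def subset_proportion_matrix(cohort: Cohort, subset: str,
                             condition: str | None = None) -> pd.DataFrame:
    """Individuals × clonotypes proportions within one cell subset's clonal space."""
    locus = "IGH" if subset.endswith("_B") else "TRB"
    rows, index = [], []
    for rep in cohort.iter_repertoires(locus=locus, condition=condition):
        recs = [r for r in rep.records if r.cell_subset == subset]
        if not recs:
            continue
        total = sum(r.duplicate_count for r in recs)
        rows.append({r.junction_aa: r.duplicate_count / total for r in recs})
        index.append((rep.study_id, rep.individual_id))
    if not rows:
        raise ValueError(f"no repertoires carry subset {subset!r}")
    df = pd.DataFrame(rows).fillna(0.0)
    df.index = pd.MultiIndex.from_tuples(index, names=["study_id", "individual_id"])
    return df.reindex(sorted(df.columns), axis=1)


def top_public_by_subset(cohort: Cohort, subset: str, k: int = 50,
                         condition: str | None = None,
                         min_individuals: int = 2) -> list[str]:
    """The k most frequent public clonotypes of one cell subset.

    Counts are pooled over individuals within the subset; publicity requires
    presence in >= min_individuals.  Ties break lexicographically.
    """
    locus = "IGH" if subset.endswith("_B") else "TRB"
    counts: dict[str, int] = {}
    carriers: dict[str, int] = {}
    found = False
    for rep in cohort.iter_repertoires(locus=locus, condition=condition):
        recs = [r for r in rep.records if r.cell_subset == subset]
        if recs:
            found = True
        for r in recs:
            counts[r.junction_aa] = counts.get(r.junction_aa, 0) + r.duplicate_count
            carriers[r.junction_aa] = carriers.get(r.junction_aa, 0) + 1
    if not found:
        raise ValueError(f"subset {subset!r} absent from cohort")
    public = [s for s, n in carriers.items() if n >= min_individuals]
    ranked = sorted(public, key=lambda s: (-counts[s], s))
    if len(ranked) < k:
        logger.warning("subset %s: only %d public clonotypes (< k=%d)",
                       subset, len(ranked), k)
    return ranked[:k]


def _pearson_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-columns Pearson r and two-sided t-test p over rows of X."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = Xc / (sd * np.sqrt(n - 1))
        r = Z.T @ Z
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    r[:, sd == 0] = np.nan
    r[sd == 0, :] = np.nan
    p[np.isnan(r)] = np.nan
    return r, p


def count_high_correlations(subset_matrices: dict[str, pd.DataFrame],
                            r_thresh: float, p_thresh: float = 0.05,
                            focal: tuple[str, str] | None = None) -> pd.DataFrame:
    """Count highly correlated clonotype pairs per subset-pair category.

    ``subset_matrices`` maps subset name -> individuals × clonotypes
    proportion matrix (e.g. the top-50 public clonotypes of each subset).
    All matrices are aligned on their common individuals; Pearson r and p
    are computed for every clonotype pair; a pair counts as "high" when
    r > r_thresh and p < p_thresh.  Returns one row per unordered category
    (subset_a <= subset_b) with counts, fractions, and — when ``focal`` is
    given — a 2×2 Fisher exact p comparing the focal category's fraction
    against all remaining pairs.
    """
    subsets = sorted(subset_matrices)
    common = None
    for df in subset_matrices.values():
        common = df.index if common is None else common.intersection(df.index)
    if len(common) < 4:
        raise ValueError("need >= 4 common individuals")
    mats = {s: subset_matrices[s].loc[common] for s in subsets}
    X = np.hstack([mats[s].values for s in subsets])
    labels = np.concatenate([[s] * mats[s].shape[1] for s in subsets])
    r, p = _pearson_matrix(X)
    high = (r > r_thresh) & (p < p_thresh)

    rows = []
    tallies: dict[tuple[str, str], tuple[int, int]] = {}
    for sa, sb in combinations_with_replacement(subsets, 2):
        ia = np.where(labels == sa)[0]
        ib = np.where(labels == sb)[0]
        if sa == sb:
            iu, ju = np.triu_indices(len(ia), k=1)
            sub_high = high[np.ix_(ia, ia)][iu, ju]
            sub_ok = ~np.isnan(r[np.ix_(ia, ia)][iu, ju])
        else:
            sub_high = high[np.ix_(ia, ib)].ravel()
            sub_ok = ~np.isnan(r[np.ix_(ia, ib)]).ravel()
        n_pairs = int(sub_ok.sum())
        n_high = int(sub_high[sub_ok].sum())
        tallies[(sa, sb)] = (n_high, n_pairs)
        rows.append({"subset_a": sa, "subset_b": sb, "n_pairs": n_pairs,
                     "n_high": n_high,
                     "fraction": n_high / n_pairs if n_pairs else np.nan})
    out = pd.DataFrame(rows)
    if focal is not None:
        fa = tuple(sorted(focal))
        k_f, n_f = tallies[fa]
        k_o = sum(v[0] for c, v in tallies.items() if c != fa)
        n_o = sum(v[1] for c, v in tallies.items() if c != fa)
        _, p_two = stats.fisher_exact([[k_f, n_f - k_f], [k_o, n_o - k_o]])
        _, p_greater = stats.fisher_exact([[k_f, n_f - k_f], [k_o, n_o - k_o]],
                                          alternative="greater")
        out.attrs["focal"] = fa
        out.attrs["fisher_p_two_sided"] = float(p_two)
        out.attrs["fisher_p_greater"] = float(p_greater)
    return out


def pairwise_bt_correlations(bmat: pd.DataFrame, tmat: pd.DataFrame,
                             min_n: int = 4) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Meta-analyzed Pearson correlation of every B×T clonotype pair.

    Both matrices are individuals × clonotypes with a (study_id,
    individual_id) row index.  Per study, the Pearson correlation of each
    (b, t) column pair is computed over the study's individuals (requiring
    >= min_n individuals and non-zero variance in both columns); per-study
    correlations are pooled on the Fisher-z scale with weights n - 3.
    Returns (pooled_r, n_studies) as B × T DataFrames; entries with no
    contributing study are NaN.
    """
    common = bmat.index.intersection(tmat.index)
    bmat, tmat = bmat.loc[common], tmat.loc[common]
    B, T = bmat.shape[1], tmat.shape[1]
    num = np.zeros((B, T))
    den = np.zeros((B, T))
    k_used = np.zeros((B, T), dtype=int)
    for study in common.get_level_values("study_id").unique():
        sel = common.get_level_values("study_id") == study
        n = int(sel.sum())
        if n < min_n:
            logger.warning("study %s: %d paired individuals < %d, excluded",
                           study, n, min_n)
            continue
        Xb = bmat.values[sel]
        Xt = tmat.values[sel]
        sb = Xb.std(axis=0, ddof=1)
        st = Xt.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            Zb = (Xb - Xb.mean(axis=0)) / (sb * np.sqrt(n - 1))
            Zt = (Xt - Xt.mean(axis=0)) / (st * np.sqrt(n - 1))
        r = np.clip(Zb.T @ Zt, -0.999999, 0.999999)
        valid = np.outer(sb > 0, st > 0)
        z = np.where(valid, np.arctanh(np.where(valid, r, 0.0)), 0.0)
        w = float(n - 3)
        num += np.where(valid, w * z, 0.0)
        den += np.where(valid, w, 0.0)
        k_used += valid.astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = np.tanh(num / den)
    pooled[den == 0] = np.nan
    return (pd.DataFrame(pooled, index=bmat.columns, columns=tmat.columns),
            pd.DataFrame(k_used, index=bmat.columns, columns=tmat.columns))


def cluster_correlation_matrix(
    pooled_r: pd.DataFrame,
    linkage_method: str = "complete",
    n_clusters_b: int | None = None,
    n_clusters_t: int | None = None,
    height_frac: float = 0.5,
    min_mean_abs_r: float = 0.4,
    min_size: int = 2,
    condition: str = "",
) -> list[BTClusterPair]:
    """Extract correlated B×T blocks from the pooled correlation matrix.

    B clonotypes (rows) are hierarchically clustered on the Euclidean
    distance between their correlation profiles, T clonotypes (columns)
    likewise; trees are cut at a fixed cluster count or, by default, at
    ``height_frac`` × the final merge height.  Every (B-group × T-group)
    block is scored by its mean |pooled r|; blocks with score >=
    ``min_mean_abs_r`` and both sides >= ``min_size`` are emitted best-first,
    each B/T group participating in at most one emitted pair.

    NaN entries (inestimable pairs) are imputed as 0 before clustering.
    """
    R = pooled_r.fillna(0.0)
    if R.shape[0] < 2 or R.shape[1] < 2:
        raise ValueError("correlation matrix must be at least 2×2")

    def _cut(X: np.ndarray, k: int | None) -> np.ndarray:
        Z = linkage(X, method=linkage_method, metric="euclidean")
        if k is not None:
            return fcluster(Z, t=k, criterion="maxclust")
        return fcluster(Z, t=height_frac * Z[-1, 2], criterion="distance")

    lab_b = _cut(R.values, n_clusters_b)
    lab_t = _cut(R.values.T, n_clusters_t)

    candidates = []
    for cb in np.unique(lab_b):
        ib = np.where(lab_b == cb)[0]
        if len(ib) < min_size:
            continue
        for ct in np.unique(lab_t):
            it = np.where(lab_t == ct)[0]
            if len(it) < min_size:
                continue
            score = float(np.abs(R.values[np.ix_(ib, it)]).mean())
            if score >= min_mean_abs_r:
                candidates.append((score, cb, ct, ib, it))
    candidates.sort(key=lambda c: -c[0])

    pairs: list[BTClusterPair] = []
    used_b: set[int] = set()
    used_t: set[int] = set()
    for score, cb, ct, ib, it in candidates:
        if cb in used_b or ct in used_t:
            continue
        used_b.add(cb)
        used_t.add(ct)
        pairs.append(BTClusterPair(
            cluster_id=len(pairs),
            b_members=[str(pooled_r.index[i]) for i in ib],
            t_members=[str(pooled_r.columns[i]) for i in it],
            mean_abs_r=score, condition=condition))
    return pairs


def sample_random_groups(pool, size: int, n_iter: int = 10000,
                         rng: np.random.Generator | None = None) -> list[tuple[str, ...]]:
    """n_iter uniform without-replacement groups of exactly ``size`` clonotypes."""
    pool = sorted(pool)
    if size > len(pool):
        raise ValueError(f"group size {size} exceeds pool size {len(pool)}")
    rng = rng or np.random.default_rng()
    arr = np.array(pool, dtype=object)
    return [tuple(arr[rng.choice(len(arr), size=size, replace=False)])
            for _ in range(n_iter)]


def clusters_to_table(pairs: list[BTClusterPair]) -> pd.DataFrame:
    """Long membership table (cluster_id, locus, junction_aa, mean_abs_r)."""
    rows = []
    for p in pairs:
        for locus, members in (("IGH", p.b_members), ("TRB", p.t_members)):
            for seq in members:
                rows.append({"cluster_id": p.cluster_id, "locus": locus,
                             "junction_aa": seq, "mean_abs_r": p.mean_abs_r,
                             "condition": p.condition})
    return pd.DataFrame(rows)


def clusters_from_table(df: pd.DataFrame) -> list[BTClusterPair]:
    """Inverse of :func:`clusters_to_table`."""
    pairs = []
    for cid, grp in df.groupby("cluster_id"):
        pairs.append(BTClusterPair(
            cluster_id=int(cid),
            b_members=sorted(grp.loc[grp["locus"] == "IGH", "junction_aa"]),
            t_members=sorted(grp.loc[grp["locus"] == "TRB", "junction_aa"]),
            mean_abs_r=float(grp["mean_abs_r"].iloc[0]) if "mean_abs_r" in grp else float("nan"),
            condition=str(grp["condition"].iloc[0]) if "condition" in grp else ""))
    return pairs


def clustered_fraction(pairs: list[BTClusterPair], public_b: set, public_t: set) -> dict:
    """Fraction of public clonotypes assigned to clusters (reported, not asserted)."""
    in_b = {s for p in pairs for s in p.b_members}
    in_t = {s for p in pairs for s in p.t_members}
    return {"fraction_b": len(in_b) / len(public_b) if public_b else float("nan"),
            "fraction_t": len(in_t) / len(public_t) if public_t else float("nan")}
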