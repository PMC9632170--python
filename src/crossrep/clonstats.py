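"""Clonality and diversity summary statistics with repertoire downsampling.

Clonality indices describe how clonal space is distributed over clonotypes:
clonal volume (number of unique clonotypes), the cumulative proportion of the
top-100 most abundant clonotypes, and the proportions occupied by
hyperexpanded (> 1% of clonal space), small (< 0.001% of clonal space) and
rare (count < 3) clones.  Diversity indices cover richness (Chao1) and
evenness (Hill numbers of order 1 and 2, Gini–Simpson, Gini coefficient).

Because all of these depend on sequencing depth, repertoires can be
downsampled to fixed sizes — by reads (hypergeometric, preserving expected
proportions) for clonality/diversity sensitivity analyses, or by unique
clonotypes (frequency information removed) for network construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import stable_rng
from .repdata import ClonotypeRecord, Cohort, Repertoire

logger = logging.getLogger(__name__)

DEFAULT_DOWNSAMPLE_SIZES = (200, 500, 1000, 2000, 5000, 8000)

METRIC_COLUMNS = [
    "clonal_volume", "top100_prop", "hyperexpanded_prop", "small_prop",
    "rare_prop", "chao1", "hill_q1", "hill_q2", "gini_simpson", "gini",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given repertoire."""


@dataclass(frozen=True)
class BinThresholds:
    """Thresholds defining the clonal-proportion bins.

    ``hyperexpanded_min`` and ``small_max`` are proportions of clonal space
    (total reads); ``rare_count_max`` is an absolute count ("fewer than
    three" reads = counts <= 2).
    """

    top_n: int = 100
    hyperexpanded_min: float = 0.01
    small_max: float = 1e-5
    rare_count_max: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.small_max < self.hyperexpanded_min <= 1:
            raise ValueError("need 0 < small_max < hyperexpanded_min <= 1")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def clonal_volume(rep: Repertoire) -> int:
    """Number of unique clonotypes (unique CDR3 amino-acid sequences)."""
    return rep.clonal_volume


def clone_fraction_bins(
    rep: Repertoire, th: BinThresholds = BinThresholds()
) -> tuple[float, float, float, float]:
    """(top_prop, hyperexpanded_prop, small_prop, rare_prop).

    ``top_prop`` sums the proportions of the ``top_n`` most abundant
    clonotypes (boundary ties broken lexicographically on junction_aa for
    determinism); the other three sum proportions over threshold-defined
    subsets.  A repertoire smaller than ``top_n`` has top_prop = 1.
    """
    p = np.asarray(rep.proportions, dtype=float)
    counts = rep.counts()
    # sort by (-proportion, junction_aa) for a deterministic top-N
    order = sorted(range(len(p)), key=lambda i: (-p[i], rep.records[i].junction_aa))
    top = float(p[order[: th.top_n]].sum())
    hyper = float(p[p > th.hyperexpanded_min].sum())
    small = float(p[p < th.small_max].sum())
    rare = float(p[counts <= th.rare_count_max].sum())
    return top, hyper, small, rare


def chao1(rep: Repertoire, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton (F1) and doubleton (F2) counts.

    Classic: S + F1^2 / (2 F2); bias-corrected (default):
    S + F1 (F1 - 1) / (2 (F2 + 1)).  The classic form with F2 = 0 falls back
    to the bias-corrected form.
    """
    counts = rep.counts()
    s = len(counts)
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if not bias_corrected and f2 > 0:
        return s + f1 * f1 / (2.0 * f2)
    if not bias_corrected:
        logger.info("chao1: F2=0, falling back to bias-corrected form")
    return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def hill_number(rep: Repertoire, q: int) -> float:
    """Hill number (effective number of clonotypes) of order q in {1, 2}.

    q=1 is exp(Shannon entropy, natural log); q=2 is inverse Simpson.
    """
    if rep.clonal_volume == 0:
        raise UndefinedMetricError("hill number undefined for empty repertoire")
    p = np.asarray(rep.proportions, dtype=float)
    p = p[p > 0]
    if q == 1:
        return float(np.exp(-(p * np.log(p)).sum()))
    if q == 2:
        return float(1.0 / (p ** 2).sum())
    raise ValueError("q must be 1 or 2")


def gini_simpson(rep: Repertoire) -> float:
    """Gini–Simpson index 1 - sum(p^2): probability of interspecific encounter."""
    p = np.asarray(rep.proportions, dtype=float)
    return float(1.0 - (p ** 2).sum())


def gini_coefficient(rep: Repertoire) -> float:
    """Gini inequality coefficient of the clonotype count distribution.

    Computed with the sorted O(n log n) identity, equal to
    sum_ij |x_i - x_j| / (2 n^2 mean(x)).
    """
    x = np.sort(rep.counts().astype(float))
    n = len(x)
    if n == 0:
        raise UndefinedMetricError("gini undefined for empty repertoire")
    if n == 1:
        return 0.0
    cum = np.cumsum(x)
    # G = (2 sum_i i*x_(i) - (n+1) sum x) / (n sum x), i = 1..n
    i = np.arange(1, n + 1)
    return float((2.0 * (i * x).sum() - (n + 1) * cum[-1]) / (n * cum[-1]))


def downsample(rep: Repertoire, size: int, mode: str = "reads",
               rng: np.random.Generator | None = None) -> Repertoire | None:
    """Downsample a repertoire to a fixed size.

    mode="clonotypes": uniform sample of unique clonotypes without
    replacement; counts discarded (set to 1), for network construction.
    mode="reads": multivariate hypergeometric sampling of reads without
    replacement; clonotypes drawn to zero are dropped.

    Returns None (with a warning) when the repertoire is too small for
    ``size``, so the individual is simply excluded at that size.
    """
    rng = rng or np.random.default_rng()
    if mode == "clonotypes":
        if size > rep.clonal_volume:
            logger.warning("%s/%s: %d clonotypes < size %d, skipped",
                           rep.individual_id, rep.locus, rep.clonal_volume, size)
            return None
        idx = rng.choice(rep.clonal_volume, size=size, replace=False)
        records = [
            ClonotypeRecord(rep.records[i].junction_aa, 1, rep.locus,
                            rep.records[i].cell_subset)
            for i in sorted(idx)
        ]
    elif mode == "reads":
        counts = rep.counts()
        total = int(counts.sum())
        if size > total:
            logger.warning("%s/%s: %d reads < size %d, skipped",
                           rep.individual_id, rep.locus, total, size)
            return None
        new_counts = rng.multivariate_hypergeometric(counts, size)
        records = [
            ClonotypeRecord(rep.records[i].junction_aa, int(c), rep.locus,
                            rep.records[i].cell_subset)
            for i, c in enumerate(new_counts) if c > 0
        ]
    else:
        raise ValueError("mode must be 'clonotypes' or 'reads'")
    return Repertoire(rep.individual_id, rep.study_id, rep.condition,
                      rep.locus, records)


def summarize_repertoire(rep: Repertoire, th: BinThresholds = BinThresholds()) -> dict:
    """All ten clonality/diversity metrics for one repertoire."""
    top, hyper, small, rare = clone_fraction_bins(rep, th)
    return {
        "clonal_volume": clonal_volume(rep),
        "top100_prop": top,
        "hyperexpanded_prop": hyper,
        "small_prop": small,
        "rare_prop": rare,
        "chao1": chao1(rep),
        "hill_q1": hill_number(rep, 1),
        "hill_q2": hill_number(rep, 2),
        "gini_simpson": gini_simpson(rep),
        "gini": gini_coefficient(rep),
    }


def summarize_cohort(
    cohort: Cohort,
    th: BinThresholds = BinThresholds(),
    sizes: tuple[int, ...] = (),
    mode: str = "reads",
    seed: int = 0,
) -> pd.DataFrame:
    """One metrics row per (study, individual, locus, size in {full} + sizes).

    Downsampled rows are deterministic given ``seed``; repertoires too small
    for a size are flagged (``skipped`` column) rather than aborting the run.
    """
    rows = []
    for rep in cohort.iter_repertoires():
        keys = {"study_id": rep.study_id, "individual_id": rep.individual_id,
                "condition": rep.condition, "locus": rep.locus}
        rows.append({**keys, "size": "full", "skipped": False,
                     **summarize_repertoire(rep, th)})
        for size in sizes:
            rng = stable_rng(seed, rep.study_id, rep.individual_id,
                             rep.locus, size)
            sub = downsample(rep, size, mode=mode, rng=rng)
            if sub is None:
                rows.append({**keys, "size": size, "skipped": True})
            else:
                rows.append({**keys, "size": size, "skipped": False,
                             **summarize_repertoire(sub, th)})
    return pd.DataFrame(rows)
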