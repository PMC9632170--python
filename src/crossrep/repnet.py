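"""Levenshtein-distance clonotype similarity networks and global metrics.

Each unique CDR3 sequence is a node; two distinct sequences are connected
when their Levenshtein distance is at most ``max_dist`` (default 3).  Graphs
are unweighted and undirected, built after removing frequency information.
Six global metrics summarize each graph: degree assortativity, average
degree, average clustering coefficient, density, and local and global
efficiency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from ._util import stable_rng
from .clonstats import downsample
from .repdata import Repertoire

logger = logging.getLogger(__name__)

METRIC_NAMES = ["assortativity", "avg_degree", "avg_clustering", "density",
                "local_efficiency", "global_efficiency"]


class UndefinedMetricError(ValueError):
    pass


def levenshtein(a: str, b: str, max_dist: int | None = None) -> int:
    """Unit-cost edit distance (insert/delete/substitute).

    With ``max_dist`` set, returns ``max_dist + 1`` as soon as the distance
    is known to exceed it (banded computation).
    """
    if a == b:
        return 0
    if max_dist is not None:
        res = edlib.align(a, b, task="distance", k=max_dist)
        d = res["editDistance"]
        return max_dist + 1 if d == -1 else d
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class ClonotypeGraph:
    """Undirected LD-threshold graph over unique CDR3 sequences."""

    graph: nx.Graph
    max_dist: int = 3
    downsample_size: int | None = None
    seed: int | None = None

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


def build_ld_graph(seqs, max_dist: int = 3) -> ClonotypeGraph:
    """Build the LD-threshold graph over a set of unique sequences.

    Edges connect distinct sequences with 1 <= LD <= max_dist.  Candidate
    pairs are pruned by length difference (|len(a) - len(b)| > max_dist
    implies LD > max_dist), which is exact.
    """
    if max_dist < 1:
        raise ValueError("max_dist must be >= 1")
    seqs = sorted(set(seqs))
    g = nx.Graph()
    g.add_nodes_from(seqs)
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)
    lengths = sorted(by_len)
    for la in lengths:
        for lb in lengths:
            if lb < la or lb - la > max_dist:
                continue
            for a in by_len[la]:
                for b in by_len[lb]:
                    if lb == la and b <= a:
                        continue
                    if levenshtein(a, b, max_dist=max_dist) <= max_dist:
                        g.add_edge(a, b)
    return ClonotypeGraph(graph=g, max_dist=max_dist)


def network_metrics(cg: ClonotypeGraph | nx.Graph) -> dict[str, float]:
    """The six global network metrics.

    Conventions: disconnected pairs contribute 0 to global efficiency
    (1/inf = 0); nodes of degree < 2 contribute 0 to clustering and local
    efficiency; degree assortativity is NaN when the degree variance at edge
    endpoints is zero (e.g. regular graphs).
    """
    g = cg.graph if isinstance(cg, ClonotypeGraph) else cg
    n = g.number_of_nodes()
    if n < 2:
        raise UndefinedMetricError("metrics need >= 2 nodes")
    m = g.number_of_edges()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # nan assortativity on regular graphs
        try:
            assort = float(nx.degree_assortativity_coefficient(g)) if m else float("nan")
        except (ValueError, ZeroDivisionError):
            assort = float("nan")
    return {
        "assortativity": assort,
        "avg_degree": 2.0 * m / n,
        "avg_clustering": float(nx.average_clustering(g)),
        "density": float(nx.density(g)),
        "local_efficiency": float(nx.local_efficiency(g)),
        "global_efficiency": float(nx.global_efficiency(g)),
    }


def network_summary(rep: Repertoire, sizes, max_dist: int = 3,
                    seed: int = 0) -> pd.DataFrame:
    """Network metrics per downsample size (mode=clonotypes, frequency removed).

    Sizes exceeding the clonal volume are skipped with a warning; rows are
    deterministic given ``seed``.
    """
    rows = []
    for size in sizes:
        rng = stable_rng(seed, rep.study_id, rep.individual_id, rep.locus, size)
        sub = downsample(rep, size, mode="clonotypes", rng=rng)
        if sub is None:
            continue
        cg = build_ld_graph(sub.sequences, max_dist=max_dist)
        rows.append({"study_id": rep.study_id, "individual_id": rep.individual_id,
                     "condition": rep.condition, "locus": rep.locus, "size": size,
                     **network_metrics(cg)})
    return pd.DataFrame(rows)


def network_summary_cohort(cohort, sizes, max_dist: int = 3,
                           seed: int = 0) -> pd.DataFrame:
    frames = [network_summary(rep, sizes, max_dist=max_dist, seed=seed)
              for rep in cohort.iter_repertoires()]
    frames = [f for f in frames if not f.empty]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
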