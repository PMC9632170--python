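"""Antigen annotation of T clonotype clusters.

Clustered TRB CDR3 sequences are matched exactly against an
antigen-annotated CDR3β table (the export format of public databases such
as McPAS-TCR and VDJdb: one row per CDR3/antigen-category pair).  Per
category, the fraction of matching clonotypes inside a cluster is compared
to the fraction in the background pool of public T clonotypes, giving a
fold enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .repdata import is_valid_junction

logger = logging.getLogger(__name__)

#: accepted column names: canonical -> aliases (McPAS / VDJdb slim dialects)
ANTIGEN_COLUMN_ALIASES = {
    "cdr3b_aa": ("cdr3b_aa", "CDR3.beta.aa", "cdr3", "CDR3"),
    "antigen_category": ("antigen_category", "Pathology", "antigen.species",
                         "Category"),
}


@dataclass
class AntigenDB:
    """Deduplicated (CDR3β, antigen category) annotations."""

    records: set = field(default_factory=set)  # {(cdr3b_aa, category)}

    @property
    def categories(self) -> list[str]:
        return sorted({c for _, c in self.records})

    def sequences_of(self, category: str) -> set[str]:
        return {s for s, c in self.records if c == category}


def load_antigen_table(path: str | Path, categories=None,
                       aliases=ANTIGEN_COLUMN_ALIASES) -> AntigenDB:
    """Load an antigen-annotation TSV into an AntigenDB.

    Rows with invalid CDR3 strings are dropped with a warning; duplicate
    (cdr3, category) pairs collapse; an optional ``categories`` filter
    retains only the configured antigen categories.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in df.columns:
                colmap[canonical] = name
                break
    missing = set(aliases) - set(colmap)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)} "
                         f"(have {list(df.columns)})")
    db = AntigenDB()
    n_bad = 0
    for _, row in df.iterrows():
        seq = str(row[colmap["cdr3b_aa"]])
        cat = str(row[colmap["antigen_category"]])
        if not is_valid_junction(seq):
            n_bad += 1
            continue
        if categories is not None and cat not in categories:
            continue
        db.records.add((seq, cat))
    if n_bad:
        logger.warning("%s: dropped %d rows with invalid CDR3", path, n_bad)
    return db


def cluster_antigen_enrichment(cluster_t, background, db: AntigenDB) -> pd.DataFrame:
    """Per-category fold enrichment of antigen-annotated sequences.

    For category c: f_cluster = |cluster ∩ db_c| / |cluster|,
    f_background = |background ∩ db_c| / |background|, enrichment =
    f_cluster / f_background (NaN when the background fraction is 0).
    Matching is exact on the CDR3β amino-acid string.
    """
    cluster_t = set(cluster_t)
    background = set(background)
    if not cluster_t:
        raise ValueError("empty cluster")
    if not cluster_t <= background:
        raise ValueError("cluster must be a subset of the background pool")
    rows = []
    for cat in db.categories:
        seqs = db.sequences_of(cat)
        f_cl = len(cluster_t & seqs) / len(cluster_t)
        f_bg = len(background & seqs) / len(background)
        rows.append({
            "category": cat,
            "n_cluster_matches": len(cluster_t & seqs),
            "f_cluster": f_cl,
            "f_background": f_bg,
            "enrichment": f_cl / f_bg if f_bg > 0 else float("nan"),
        })
    return pd.DataFrame(rows)
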