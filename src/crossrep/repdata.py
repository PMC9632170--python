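"""Domain types and I/O for clonotype repertoires.

A *repertoire* is one individual's set of unique CDR3 amino-acid clonotypes
for one receptor chain (IGH for B cells, TRB for T cells), each with a
read/cell count and a normalized clonal proportion.  Cohorts group paired
B/T repertoires across studies and conditions via a manifest.

Input tables follow the AIRR Rearrangement TSV convention (``junction_aa``,
``duplicate_count``, ``locus``); a configurable alias map accepts MiXCR-style
exports (``aaSeqCDR3``, ``cloneCount``).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

LOCI = ("IGH", "TRB")
CONDITIONS = ("healthy", "disease")

B_SUBSETS = ("naive_B", "memory_B")
T_SUBSETS = ("naive_CD4", "memory_CD4", "naive_CD8", "memory_CD8")
CELL_SUBSETS = B_SUBSETS + T_SUBSETS

#: default column aliases: canonical AIRR name -> accepted alternatives
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "junction_aa": ("junction_aa", "aaSeqCDR3", "cdr3aa", "CDR3.aa"),
    "duplicate_count": ("duplicate_count", "cloneCount", "count", "Clones"),
    "locus": ("locus",),
    "v_call": ("v_call", "allVHitsWithScore", "v"),
    "j_call": ("j_call", "allJHitsWithScore", "j"),
    "cell_subset": ("cell_subset", "subset"),
}


class RepertoireFormatError(ValueError):
    """Raised for malformed repertoire tables or manifests."""


class EmptyRepertoireError(ValueError):
    """Raised when no valid clonotype rows survive filtering."""


def is_valid_junction(seq: str) -> bool:
    """True if ``seq`` is a non-empty string over the 20-letter AA alphabet."""
    return isinstance(seq, str) and bool(_AA_RE.match(seq))


@dataclass(frozen=True)
class ClonotypeRecord:
    """A unique CDR3 clonotype with its abundance within one repertoire."""

    junction_aa: str
    duplicate_count: int
    locus: str
    cell_subset: str | None = None
    v_call: str | None = None
    j_call: str | None = None

    def __post_init__(self) -> None:
        if not is_valid_junction(self.junction_aa):
            raise ValueError(f"invalid junction_aa: {self.junction_aa!r}")
        if self.duplicate_count < 1:
            raise ValueError("duplicate_count must be >= 1")
        if self.locus not in LOCI:
            raise ValueError(f"locus must be one of {LOCI}")
        if self.cell_subset is not None:
            allowed = B_SUBSETS if self.locus == "IGH" else T_SUBSETS
            if self.cell_subset not in allowed:
                raise ValueError(
                    f"cell_subset {self.cell_subset!r} inconsistent with locus {self.locus}"
                )


@dataclass
class Repertoire:
    """One individual × one chain clonotype table with counts and proportions.

    Clonotypes are keyed on ``junction_aa`` alone (identical CDR3s are merged
    regardless of V/J annotation, matching the public-clonotype definition
    used downstream).  ``proportions[i]`` is ``records[i].duplicate_count``
    divided by the total count; the *clonal volume* is ``len(records)``.
    """

    individual_id: str
    study_id: str
    condition: str
    locus: str
    records: list[ClonotypeRecord]
    proportions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        seqs = [r.junction_aa for r in self.records]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate junction_aa within a repertoire")
        counts = np.array([r.duplicate_count for r in self.records], dtype=float)
        if self.proportions is None:
            self.proportions = counts / counts.sum() if len(counts) else counts
        if len(self.records) and abs(float(self.proportions.sum()) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    @property
    def clonal_volume(self) -> int:
        return len(self.records)

    @property
    def total_count(self) -> int:
        return sum(r.duplicate_count for r in self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.junction_aa for r in self.records]

    def counts(self) -> np.ndarray:
        return np.array([r.duplicate_count for r in self.records], dtype=np.int64)

    def proportion_of(self, junction_aa: str) -> float:
        """Clonal proportion of ``junction_aa``; 0.0 if absent."""
        for rec, p in zip(self.records, self.proportions):
            if rec.junction_aa == junction_aa:
                return float(p)
        return 0.0


@dataclass
class Cohort:
    """Paired repertoires across studies, keyed by (study, individual, locus)."""

    repertoires: dict[tuple[str, str, str], Repertoire] = field(default_factory=dict)
    covariates: dict[tuple[str, str], dict] = field(default_factory=dict)

    def add(self, rep: Repertoire) -> None:
        key = (rep.study_id, rep.individual_id, rep.locus)
        if key in self.repertoires:
            raise RepertoireFormatError(f"duplicate repertoire {key}")
        self.repertoires[key] = rep

    def get(self, study_id: str, individual_id: str, locus: str) -> Repertoire | None:
        return self.repertoires.get((study_id, individual_id, locus))

    def individuals(self, study_id: str | None = None) -> list[tuple[str, str]]:
        keys = {(s, i) for s, i, _ in self.repertoires}
        if study_id is not None:
            keys = {k for k in keys if k[0] == study_id}
        return sorted(keys)

    def studies(self) -> list[str]:
        return sorted({s for s, _, _ in self.repertoires})

    def is_paired(self, study_id: str, individual_id: str) -> bool:
        return all((study_id, individual_id, loc) in self.repertoires for loc in LOCI)

    def paired_individuals(self, study_id: str | None = None) -> list[tuple[str, str]]:
        return [k for k in self.individuals(study_id) if self.is_paired(*k)]

    def condition_of(self, study_id: str, individual_id: str) -> str:
        for loc in LOCI:
            rep = self.repertoires.get((study_id, individual_id, loc))
            if rep is not None:
                return rep.condition
        raise KeyError((study_id, individual_id))

    def subset(self, condition: str) -> "Cohort":
        """Cohort restricted to one condition group."""
        sub = Cohort()
        for key, rep in self.repertoires.items():
            if rep.condition == condition:
                sub.repertoires[key] = rep
        for k, v in self.covariates.items():
            if any((k[0], k[1], loc) in sub.repertoires for loc in LOCI):
                sub.covariates[k] = v
        return sub

    def iter_repertoires(self, locus: str | None = None,
                         condition: str | None = None) -> Iterable[Repertoire]:
        for (s, i, loc) in sorted(self.repertoires):
            rep = self.repertoires[(s, i, loc)]
            if locus is not None and loc != locus:
                continue
            if condition is not None and rep.condition != condition:
                continue
            yield rep


def _resolve_columns(columns: Iterable[str],
                     aliases: Mapping[str, tuple[str, ...]]) -> dict[str, str]:
    present = {}
    cols = list(columns)
    for canonical, names in aliases.items():
        for name in names:
            if name in cols:
                present[canonical] = name
                break
    return present


def read_airr_repertoire(
    path: str | Path,
    locus: str,
    individual_id: str = "",
    study_id: str = "",
    condition: str = "healthy",
    aliases: Mapping[str, tuple[str, ...]] | None = None,
) -> Repertoire:
    """Read a clonotype table (AIRR Rearrangement TSV subset) into a Repertoire.

    Rows with identical ``junction_aa`` are merged by summing counts.
    Nonproductive junctions (containing ``*`` or ``_``) and rows outside the
    20-letter alphabet are dropped with a logged count.  Missing or zero
    counts default to 1 (single-cell convention).
    """
    if locus not in LOCI:
        raise ValueError(f"locus must be one of {LOCI}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap = _resolve_columns(df.columns, aliases or COLUMN_ALIASES)
    if "junction_aa" not in colmap:
        raise RepertoireFormatError(f"{path}: no junction_aa column (have {list(df.columns)})")

    seqs = df[colmap["junction_aa"]].astype(str)
    if "duplicate_count" in colmap:
        counts = pd.to_numeric(df[colmap["duplicate_count"]], errors="coerce")
    else:
        counts = pd.Series(np.ones(len(df)))
    counts = counts.fillna(1).clip(lower=1).astype(np.int64)

    valid = seqs.map(is_valid_junction)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("%s: dropped %d nonproductive/invalid rows", path, n_dropped)

    merged = (
        pd.DataFrame({"junction_aa": seqs[valid], "duplicate_count": counts[valid]})
        .groupby("junction_aa", sort=True)["duplicate_count"].sum()
    )
    if "cell_subset" in colmap:
        subsets = (
            pd.DataFrame({"junction_aa": seqs[valid],
                          "cell_subset": df.loc[valid.index[valid], colmap["cell_subset"]]})
            .dropna().drop_duplicates("junction_aa").set_index("junction_aa")["cell_subset"]
        )
    else:
        subsets = pd.Series(dtype=str)

    if merged.empty:
        raise EmptyRepertoireError(f"{path}: no valid clonotype rows")

    records = [
        ClonotypeRecord(
            junction_aa=seq,
            duplicate_count=int(cnt),
            locus=locus,
            cell_subset=subsets.get(seq) if not subsets.empty else None,
        )
        for seq, cnt in merged.items()
    ]
    return Repertoire(individual_id=individual_id, study_id=study_id,
                      condition=condition, locus=locus, records=records)


def write_airr_repertoire(rep: Repertoire, path: str | Path) -> None:
    """Write a Repertoire as an AIRR-style TSV; round-trips through the reader."""
    if not rep.records:
        logger.warning("writing empty repertoire to %s", path)
    df = pd.DataFrame(
        {
            "junction_aa": [r.junction_aa for r in rep.records],
            "duplicate_count": [r.duplicate_count for r in rep.records],
            "locus": [r.locus for r in rep.records],
            "cell_subset": [r.cell_subset or "" for r in rep.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a manifest (YAML list or TSV).

    Each entry needs ``study_id``, ``individual_id``, ``condition``, and at
    least one of ``igh_path`` / ``trb_path`` (relative paths are resolved
    against the manifest's directory); optional ``q30_fraction`` in [0, 1].
    Individuals with only one locus are loaded but flagged unpaired and
    excluded from cross-receptor analyses downstream.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.suffix in {".yaml", ".yml"}:
        with open(manifest_path) as fh:
            entries = yaml.safe_load(fh)
        if isinstance(entries, dict):
            entries = entries.get("individuals", [])
    else:
        entries = pd.read_csv(manifest_path, sep="\t").to_dict("records")

    cohort = Cohort()
    base = manifest_path.parent
    for entry in entries:
        study = str(entry["study_id"])
        indiv = str(entry["individual_id"])
        cond = str(entry["condition"])
        if cond not in CONDITIONS:
            raise RepertoireFormatError(f"unknown condition {cond!r} for {study}/{indiv}")
        q30 = entry.get("q30_fraction")
        if q30 is not None and not (isinstance(q30, float) and math.isnan(q30)):
            q30 = float(q30)
            if not 0.0 <= q30 <= 1.0:
                raise RepertoireFormatError(
                    f"q30_fraction {q30} out of [0,1] for {study}/{indiv}")
            cohort.covariates[(study, indiv)] = {"q30_fraction": q30}
        loaded_any = False
        for locus, key in (("IGH", "igh_path"), ("TRB", "trb_path")):
            p = entry.get(key)
            if p is None or (isinstance(p, float) and math.isnan(p)) or p == "":
                continue
            rep = read_airr_repertoire(base / p, locus, individual_id=indiv,
                                       study_id=study, condition=cond)
            cohort.add(rep)
            loaded_any = True
        if not loaded_any:
            raise RepertoireFormatError(f"{study}/{indiv}: no locus file given")

    for study in cohort.studies():
        pairs = cohort.paired_individuals(study)
        total = cohort.individuals(study)
        logger.info("study %s: %d individuals (%d paired)", study, len(total), len(pairs))
    return cohort
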