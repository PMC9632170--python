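"""Sequence features of clonotype groups and discrete motif enrichment.

Clusters of clonotypes are characterized by (i) their mean pairwise
Levenshtein distance, (ii) averages of per-residue physicochemical
properties (the ten Kidera factors plus charge, core/interior propensity,
disorder, Miyazawa–Jernigan contact energy, hydropathy, volume, polarity),
and (iii) contiguous amino-acid motifs enriched in the cluster relative to
the remaining public clonotypes (Fisher exact on per-sequence
presence/absence).  Observed cluster values are compared against null
distributions built from 10,000 random, size-matched groups of public
clonotypes via two-sample Kolmogorov–Smirnov tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .publiccluster import sample_random_groups
from .repnet import levenshtein

# -- per-residue property scales ------------------------------------------
# Kidera et al. (1985): ten orthogonal factors summarizing 188 physical
# properties; rows are residues, columns KF1..KF10.
_KIDERA = {
    "A": (-1.56, -1.67, -0.97, -0.27, -0.93, -0.78, -0.20, -0.08, 0.21, -0.48),
    "R": (0.22, 1.27, 1.37, 1.87, -1.70, 0.46, 0.92, -0.39, 0.23, 0.93),
    "N": (1.14, -0.07, -0.12, 0.81, 0.18, 0.37, -0.09, 1.23, 1.10, -1.73),
    "D": (0.58, -0.22, -1.58, 0.81, -0.92, 0.15, -1.52, 0.47, 0.76, 0.70),
    "C": (0.12, -0.89, 0.45, -1.05, -0.71, 2.41, 1.52, -0.69, 1.13, 1.10),
    "Q": (-0.47, 0.24, 0.07, 1.10, 1.10, 0.59, 0.84, -0.71, -0.03, -2.33),
    "E": (-1.45, 0.19, -1.61, 1.17, -1.31, 0.40, 0.04, 0.38, -0.35, -0.12),
    "G": (1.46, -1.96, -0.23, -0.16, 0.10, -0.11, 1.32, 2.36, -1.66, 0.46),
    "H": (-0.41, 0.52, -0.28, 0.28, 1.61, 1.01, -1.85, 0.47, 1.13, 1.63),
    "I": (-0.73, -0.16, 1.79, -0.77, -0.54, 0.03, -0.83, 0.51, 0.66, -1.78),
    "L": (-1.04, 0.00, -0.24, -1.10, -0.55, -2.05, 0.96, -0.76, 0.45, 0.93),
    "K": (-0.34, 0.82, -0.23, 1.70, 1.54, -1.62, 1.15, -0.08, -0.48, 0.60),
    "M": (-1.40, 0.18, -0.42, -0.73, 2.00, 1.52, 0.26, 0.11, -1.27, 0.27),
    "F": (-0.21, 0.98, -0.36, -1.43, 0.22, -0.81, 0.67, 1.10, 1.71, -0.44),
    "P": (2.06, -0.33, -1.15, -0.75, 0.88, -0.45, 0.30, -2.30, 0.74, -0.28),
    "S": (0.81, -1.08, 0.16, 0.42, -0.21, -0.43, -1.89, -1.15, -0.97, -0.23),
    "T": (0.26, -0.70, 1.21, 0.63, -0.10, 0.21, 0.24, -1.15, -0.56, 0.19),
    "W": (0.30, 2.10, -0.72, -1.57, -1.16, 0.57, -0.48, -0.40, -2.30, -0.60),
    "Y": (1.38, 1.48, 0.80, -0.56, 0.00, -0.68, -0.31, 1.03, -0.05, 0.53),
    "V": (-0.74, -0.71, 2.04, -0.40, 0.50, -0.81, -1.07, 0.06, -0.46, 0.65),
}

_SCALES = {
    # net side-chain charge at physiological pH (H treated as neutral)
    "charge": {"R": 1, "K": 1, "D": -1, "E": -1},
    # Kyte & Doolittle (1982) hydropathy
    "hydropathy": {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
                   "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
                   "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
                   "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2},
    # Zamyatnin (1972) residue volume, cubic angstroms
    "volume": {"A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
               "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
               "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
               "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0},
    # Grantham (1974) polarity
    "polarity": {"A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5,
                 "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2,
                 "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0,
                 "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9},
    # TOP-IDP intrinsic disorder propensity (Campen et al. 2008)
    "disorder": {"W": -0.884, "F": -0.697, "Y": -0.510, "I": -0.486,
                 "M": -0.397, "L": -0.326, "V": -0.121, "C": -0.02,
                 "N": 0.007, "A": 0.06, "T": 0.059, "G": 0.166, "R": 0.180,
                 "D": 0.192, "H": 0.303, "Q": 0.318, "S": 0.341, "K": 0.586,
                 "E": 0.736, "P": 0.987},
    # Miyazawa & Jernigan (1996) self-contact energies (commonly tabulated)
    "mjenergy": {"C": -5.44, "M": -5.46, "F": -7.26, "I": -6.54, "L": -7.04,
                 "V": -5.52, "W": -5.06, "Y": -4.17, "A": -2.72, "G": -2.24,
                 "T": -2.12, "S": -1.67, "N": -1.68, "Q": -1.54, "D": -1.21,
                 "E": -1.40, "H": -3.05, "R": -1.55, "K": -0.12, "P": -1.75},
    # Janin (1979) interior (buried) propensity, used as the "core" scale
    "core": {"A": 0.3, "R": -1.4, "N": -0.5, "D": -0.6, "C": 0.9, "Q": -0.7,
             "E": -0.7, "G": 0.3, "H": -0.1, "I": 0.7, "L": 0.5, "K": -1.8,
             "M": 0.4, "F": 0.5, "P": -0.3, "S": -0.1, "T": -0.2, "W": 0.3,
             "Y": -0.4, "V": 0.6},
}


class PropertyTable:
    """Per-residue physicochemical property values for the 20 amino acids."""

    def __init__(self) -> None:
        self.values: dict[str, dict[str, float]] = {}
        for i in range(10):
            self.values[f"KF{i + 1}"] = {aa: v[i] for aa, v in _KIDERA.items()}
        for name, scale in _SCALES.items():
            self.values[name] = {aa: float(scale.get(aa, 0.0)) for aa in _KIDERA}
        self.provenance = ("Kidera 1985 factors; Kyte-Doolittle hydropathy; "
                           "Zamyatnin volume; Grantham polarity; TOP-IDP "
                           "disorder; Miyazawa-Jernigan self-contact energy; "
                           "Janin interior propensity; charge #(R,K)-#(D,E)")

    @property
    def properties(self) -> list[str]:
        return list(self.values)

    def checksum(self) -> str:
        blob = repr(sorted((p, sorted(d.items())) for p, d in self.values.items()))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


DEFAULT_PROPERTIES = PropertyTable()


@dataclass
class MotifHit:
    """A contiguous motif with its in/out-group presence counts."""

    pattern: str
    k_in: int
    n_in: int
    k_out: int
    n_out: int
    enrichment_ratio: float  # NaN when k_out = 0 ("N/A")
    p: float
    q: float = float("nan")


@dataclass
class NullDistribution:
    """Feature averages over random size-matched public-clonotype groups."""

    size: int
    n_iter: int
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    def percentile_of(self, feature: str, value: float) -> float:
        """Fraction of null group averages <= value."""
        ref = self.samples[feature].values
        return float(np.mean(ref <= value))


def mean_pairwise_ld(group) -> float:
    """Mean Levenshtein distance over all unordered sequence pairs."""
    seqs = list(group)
    if len(seqs) < 2:
        raise ValueError("mean pairwise LD needs >= 2 sequences")
    total = 0
    n = 0
    for i, a in enumerate(seqs):
        for b in seqs[i + 1:]:
            total += levenshtein(a, b)
            n += 1
    return total / n


def sequence_property_mean(seq: str, prop: str,
                           table: PropertyTable = DEFAULT_PROPERTIES) -> float:
    """Mean per-residue value of one property over a sequence."""
    scale = table.values.get(prop)
    if scale is None:
        raise KeyError(f"unknown property {prop!r}")
    try:
        return float(np.mean([scale[aa] for aa in seq]))
    except KeyError as exc:
        raise KeyError(f"residue {exc} not in property table") from exc


def group_property_mean(group, prop: str,
                        table: PropertyTable = DEFAULT_PROPERTIES) -> float:
    """Unweighted mean over the group's sequences of the per-sequence mean."""
    seqs = list(group)
    if not seqs:
        raise ValueError("empty group")
    return float(np.mean([sequence_property_mean(s, prop, table) for s in seqs]))


def group_feature_stats(group, properties=None,
                        table: PropertyTable = DEFAULT_PROPERTIES) -> dict:
    """mean_pairwise_ld plus all (or selected) property averages for a group."""
    props = properties or table.properties
    out = {"mean_pairwise_ld": mean_pairwise_ld(group)}
    for p in props:
        out[p] = group_property_mean(group, p, table)
    return out


def null_feature_distribution(pool, size: int, n_iter: int = 10000,
                              properties=None,
                              table: PropertyTable = DEFAULT_PROPERTIES,
                              rng: np.random.Generator | None = None,
                              _ld_cache: dict | None = None) -> NullDistribution:
    """Feature averages over ``n_iter`` random groups of ``size`` clonotypes.

    Pairwise distances and per-sequence property values are precomputed over
    the pool once, so the 10,000 group averages reduce to indexed means;
    ``_ld_cache`` lets callers reuse the pool distance matrix across sizes.
    """
    pool = sorted(pool)
    props = properties or table.properties
    rng = rng or np.random.default_rng()
    groups = sample_random_groups(pool, size, n_iter=n_iter, rng=rng)
    index = {s: i for i, s in enumerate(pool)}
    G = np.array([[index[s] for s in g] for g in groups], dtype=np.intp)

    cache_key = ("ldmat", tuple(pool))
    if _ld_cache is not None and cache_key in _ld_cache:
        D = _ld_cache[cache_key]
    else:
        n = len(pool)
        D = np.zeros((n, n), dtype=np.int32)
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = levenshtein(pool[i], pool[j])
        if _ld_cache is not None:
            _ld_cache[cache_key] = D

    data = {}
    npairs = size * (size - 1)
    data["mean_pairwise_ld"] = np.array(
        [D[np.ix_(g, g)].sum() / npairs for g in G])
    for p in props:
        v = np.array([sequence_property_mean(s, p, table) for s in pool])
        data[p] = v[G].mean(axis=1)
    return NullDistribution(size=size, n_iter=n_iter, samples=pd.DataFrame(data))


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov D and p (exact for small samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def motif_enrichment(k_in: int, n_in: int, k_out: int, n_out: int) -> MotifHit:
    """Enrichment ratio (k_in/n_in)/(k_out/n_out) and one-sided Fisher p.

    The ratio is NaN when the motif never occurs outside the group
    (the "N/A" convention for out-of-group zero counts).
    """
    if n_in <= 0 or n_out <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k_in <= n_in and 0 <= k_out <= n_out):
        raise ValueError("inconsistent counts")
    ratio = float("nan") if k_out == 0 else (k_in / n_in) / (k_out / n_out)
    _, p = stats.fisher_exact([[k_in, n_in - k_in], [k_out, n_out - k_out]],
                              alternative="greater")
    return MotifHit(pattern="", k_in=k_in, n_in=n_in, k_out=k_out, n_out=n_out,
                    enrichment_ratio=ratio, p=float(p))


def scan_motifs(in_group, out_group, w_min: int = 3, w_max: int = 10,
                alpha: float = 0.05) -> list[MotifHit]:
    """Exhaustive contiguous-motif enrichment scan.

    Candidate motifs are substrings of widths ``w_min``..``w_max`` present
    (sequence-level, counted once per sequence) in at least two in-group
    sequences.  Each candidate gets a one-sided Fisher exact test on
    presence counts; hits with BH-adjusted p < alpha are reported, after
    greedy de-duplication: a motif contained in an already-reported longer
    motif of greater or equal significance is suppressed.
    """
    in_group = sorted(set(in_group))
    out_group = sorted(set(out_group))
    if not in_group or not out_group:
        raise ValueError("both groups must be non-empty")
    n_in, n_out = len(in_group), len(out_group)

    presence: dict[str, int] = {}
    for seq in in_group:
        subs = {seq[i:i + w]
                for w in range(w_min, w_max + 1)
                for i in range(len(seq) - w + 1)}
        for sub in subs:
            presence[sub] = presence.get(sub, 0) + 1
    candidates = sorted(s for s, k in presence.items() if k >= 2)
    if not candidates:
        return []

    hits = []
    for pat in candidates:
        k_out = sum(pat in s for s in out_group)
        hit = motif_enrichment(presence[pat], n_in, k_out, n_out)
        hit.pattern = pat
        hits.append(hit)
    # FDR family = every enumerated pattern, not only those passing the
    # >= 2 support filter: patterns seen once are implicitly tested with
    # p = 1, otherwise singleton chance collisions pass at small alpha.
    from .metacorr import bh_fdr
    n_pad = len(presence) - len(hits)
    qs = bh_fdr([h.p for h in hits] + [1.0] * n_pad)[: len(hits)]
    for h, q in zip(hits, qs):
        h.q = float(q)
    sig = [h for h in hits if h.q < alpha]
    sig.sort(key=lambda h: (h.p, -len(h.pattern), h.pattern))
    kept: list[MotifHit] = []
    for h in sig:
        if any(h.pattern in other.pattern and other.p <= h.p for other in kept):
            continue
        kept.append(h)
    return kept


def motif_table(hits: list[MotifHit]) -> pd.DataFrame:
    """Motif hits as a table with in/out proportions and enrichment ratios."""
    return pd.DataFrame([{
        "pattern": h.pattern,
        "pr_in_group": f"{h.k_in}/{h.n_in}",
        "pr_outside_group": f"{h.k_out}/{h.n_out}",
        "enrichment_ratio": h.enrichment_ratio,
        "p": h.p, "q": h.q,
    } for h in hits])
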