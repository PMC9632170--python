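"""Synthetic paired BCR/TCR cohorts with known cross-receptor structure.

The generator emulates the statistical features the downstream analysis
assumes, with ground truth for recovery tests:

* heavy-tailed clonal abundances (Zipf ranks, multinomial read sampling);
* per-individual latent *size* and *diversity* factors shared between the
  IGH and TRB chains (weights ``rho_size`` / ``rho_div``), inducing B–T
  correlation of clonality/diversity statistics;
* a pool of public clonotypes per locus, each included in an individual with
  probability ``pi_public``, so clonotypes recur across individuals;
* K planted, non-overlapping B×T clonotype clusters whose member presence
  and proportions track a per-individual cluster factor u_{i,k} (loading
  ``lam``, noise ``sigma_eps``), producing correlated B/T proportion blocks;
* cluster members that are mutually similar (substitution edits within
  ``d_intra`` of a cluster seed sequence) and carry a planted motif.

One RNG stream per individual is derived by stable hashing of
(seed, replicate, study, individual), so generation is reproducible and
order-independent; ``replicate`` yields an independent cohort (new
individuals) sharing the same pools and planted clusters, for replication
analyses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._util import stable_rng
from .repdata import (AA_ALPHABET, B_SUBSETS, T_SUBSETS, ClonotypeRecord,
                      Cohort, Repertoire, write_airr_repertoire)

_AA = np.array(list(AA_ALPHABET))
_AA_INTERIOR = _AA  # interior residues uniform over the 20-letter alphabet
_AA_BYTES = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)


@dataclass
class SynthConfig:
    """Generator parameters (the simulated study conditions)."""

    n_studies: int = 4
    individuals_per_study: int = 30
    healthy_fraction: float = 1.0

    #: mean log repertoire size (unique clonotypes) per locus
    mu_log_size: dict = field(default_factory=lambda: {"IGH": math.log(250),
                                                       "TRB": math.log(500)})
    sigma_log_size: float = 0.4
    rho_size: float = 0.7

    #: Zipf abundance tail exponent and its shared-diversity modulation
    alpha: float = 1.0
    alpha_spread: float = 0.3
    rho_div: float = 0.5

    #: public pool sizes and inclusion probability
    P_B: int = 150
    P_T: int = 300
    pi_public: float = 0.5

    #: planted B×T clusters
    K: int = 3
    n_b_per_cluster: int = 10
    n_t_per_cluster: int = 20
    lam: float = 2.0
    sigma_eps: float = 0.5
    presence_gain: float = 2.0
    d_intra: int = 2
    motifs: tuple = ("WGQG", "YEQY", "HNDW")

    #: CDR3 length model: per-locus (mean, sd), lengths >= min_len
    length_mean: dict = field(default_factory=lambda: {"IGH": 16.0, "TRB": 14.0})
    length_sd: dict = field(default_factory=lambda: {"IGH": 2.0, "TRB": 1.5})
    min_len: int = 8

    reads_per_clonotype: int = 10
    annotate_subsets: bool = False
    seed: int = 0

    def validate(self) -> None:
        for p in (self.healthy_fraction, self.pi_public, self.rho_size, self.rho_div):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability/weight {p} outside [0,1]")
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.K * self.n_b_per_cluster > self.P_B:
            raise ValueError("cluster B members exceed public B pool")
        if self.K * self.n_t_per_cluster > self.P_T:
            raise ValueError("cluster T members exceed public T pool")
        if self.K > len(self.motifs) and self.K > 0:
            raise ValueError("need one planted motif per cluster")


@dataclass
class GroundTruth:
    """Latent factors and planted cluster memberships of a generated cohort."""

    #: per (study_id, individual_id): {"g": size factor, "h": diversity factor,
    #: "u": [K cluster factors]}
    factors: dict = field(default_factory=dict)
    cluster_b_members: list = field(default_factory=list)
    cluster_t_members: list = field(default_factory=list)
    motifs: list = field(default_factory=list)

    def membership(self, locus: str) -> dict[str, int]:
        """clonotype -> planted cluster index, for one locus."""
        members = self.cluster_b_members if locus == "IGH" else self.cluster_t_members
        return {seq: k for k, group in enumerate(members) for seq in group}


def sample_cdr3(locus: str, rng: np.random.Generator,
                length_mean: float = 14.0, length_sd: float = 1.5,
                min_len: int = 8, length: int | None = None) -> str:
    """Random CDR3: 'C' + uniform interior residues + 'F'/'W' terminus."""
    if length is None:
        length = max(min_len, int(round(rng.normal(length_mean, length_sd))))
    if length < 5:
        raise ValueError("CDR3 length must be >= 5")
    interior = "".join(_AA_INTERIOR[rng.integers(0, 20, size=length - 2)])
    last = "F" if locus == "TRB" else ("F" if rng.random() < 0.8 else "W")
    return "C" + interior + last


def _sample_many_cdr3(locus: str, n: int, rng: np.random.Generator,
                      length_mean: float, length_sd: float,
                      min_len: int) -> list[str]:
    """Vectorized batch of random CDR3s (same model as ``sample_cdr3``)."""
    lengths = np.maximum(min_len, np.round(
        rng.normal(length_mean, length_sd, size=n)).astype(int))
    width = int(lengths.max()) - 2
    codes = rng.integers(0, 20, size=(n, width))
    if locus == "TRB":
        lasts = np.full(n, "F")
    else:
        lasts = np.where(rng.random(n) < 0.8, "F", "W")
    return ["C" + _AA_BYTES[codes[i, : lengths[i] - 2]].tobytes().decode()
            + lasts[i] for i in range(n)]


def mutate_within_ld(seed_seq: str, max_edits: int,
                     rng: np.random.Generator) -> str:
    """Random variant within Levenshtein distance ``max_edits`` of the seed.

    Applies 0..max_edits random substitutions/insertions/deletions; each
    operation changes the distance by at most one, so the bound holds by
    construction.
    """
    if max_edits < 0:
        raise ValueError("max_edits must be >= 0")
    if max_edits >= len(seed_seq):
        raise ValueError("max_edits must be < sequence length")
    seq = list(seed_seq)
    n_edits = int(rng.integers(0, max_edits + 1))
    for _ in range(n_edits):
        op = rng.choice(["sub", "ins", "del"]) if len(seq) > 5 else "sub"
        if op == "sub":
            pos = int(rng.integers(1, len(seq) - 1))
            seq[pos] = str(rng.choice(_AA))
        elif op == "ins":
            pos = int(rng.integers(1, len(seq)))
            seq.insert(pos, str(rng.choice(_AA)))
        else:
            pos = int(rng.integers(1, len(seq) - 1))
            del seq[pos]
    return "".join(seq)


def _mutate_substitutions(seed_seq: str, max_edits: int, protect: range,
                          rng: np.random.Generator) -> str:
    """Substitution-only variant (LD <= max_edits), leaving ``protect`` intact."""
    seq = list(seed_seq)
    editable = [i for i in range(1, len(seq) - 1) if i not in protect]
    n_edits = int(rng.integers(0, max_edits + 1))
    for pos in rng.choice(editable, size=min(n_edits, len(editable)), replace=False):
        seq[int(pos)] = str(rng.choice(_AA))
    return "".join(seq)


def _unique_draw(draw, existing: set, max_tries: int = 200) -> str:
    for _ in range(max_tries):
        s = draw()
        if s not in existing:
            existing.add(s)
            return s
    raise RuntimeError("could not draw a unique sequence")


def _build_pools(cfg: SynthConfig) -> tuple[dict, GroundTruth]:
    """Public pools and planted cluster member sequences, from the seed only."""
    rng = stable_rng(cfg.seed, "pools")
    seen: set[str] = set()
    gt = GroundTruth(motifs=list(cfg.motifs[: cfg.K]))
    pools: dict[str, list[str]] = {}
    for locus, P, n_mem in (("IGH", cfg.P_B, cfg.n_b_per_cluster),
                            ("TRB", cfg.P_T, cfg.n_t_per_cluster)):
        members_all: list[list[str]] = []
        for k in range(cfg.K):
            motif = cfg.motifs[k]
            base = sample_cdr3(locus, rng, cfg.length_mean[locus] + 2,
                               cfg.length_sd[locus], cfg.min_len + len(motif))
            offset = int(rng.integers(2, len(base) - len(motif) - 1))
            seeded = base[:offset] + motif + base[offset + len(motif):]
            protect = range(offset, offset + len(motif))
            members = [
                _unique_draw(
                    lambda: _mutate_substitutions(seeded, cfg.d_intra, protect, rng),
                    seen)
                for _ in range(n_mem)
            ]
            members_all.append(members)
        n_bg = P - cfg.K * n_mem
        background = [
            _unique_draw(
                lambda: sample_cdr3(locus, rng, cfg.length_mean[locus],
                                    cfg.length_sd[locus], cfg.min_len), seen)
            for _ in range(n_bg)
        ]
        pools[locus] = [s for mem in members_all for s in mem] + background
        if locus == "IGH":
            gt.cluster_b_members = members_all
        else:
            gt.cluster_t_members = members_all
    return pools, gt


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def generate_cohort(cfg: SynthConfig, replicate: int = 0) -> tuple[Cohort, GroundTruth]:
    """Generate a paired multi-study cohort plus its ground truth.

    ``replicate > 0`` draws new individuals from the same planted structure
    (pools, clusters, motifs), emulating an independent replication cohort.
    """
    cfg.validate()
    pools, gt = _build_pools(cfg)
    n_cluster = {"IGH": cfg.K * cfg.n_b_per_cluster, "TRB": cfg.K * cfg.n_t_per_cluster}
    cluster_of = {loc: gt.membership(loc) for loc in ("IGH", "TRB")}
    logit_pi = math.log(cfg.pi_public / (1 - cfg.pi_public)) if 0 < cfg.pi_public < 1 \
        else (math.inf if cfg.pi_public == 1 else -math.inf)

    cohort = Cohort()
    n_healthy = int(round(cfg.healthy_fraction * cfg.individuals_per_study))
    for s in range(cfg.n_studies):
        study = f"study{s + 1}"
        for j in range(cfg.individuals_per_study):
            indiv = f"ind{j + 1:03d}"
            condition = "healthy" if j < n_healthy else "disease"
            rng = stable_rng(cfg.seed, "indiv", replicate, study, indiv)
            g = rng.normal()
            h = rng.normal()
            u = rng.normal(size=cfg.K)
            gt.factors[(study, indiv)] = {"g": float(g), "h": float(h),
                                          "u": [float(v) for v in u]}
            cohort.covariates[(study, indiv)] = {
                "q30_fraction": float(np.clip(0.93 + 0.05 * rng.normal(), 0.5, 1.0))}

            for locus in ("IGH", "TRB"):
                eps = rng.normal()
                log_size = cfg.mu_log_size[locus] + cfg.sigma_log_size * (
                    cfg.rho_size * g + math.sqrt(1 - cfg.rho_size ** 2) * eps)
                n_target = max(50, int(round(math.exp(log_size))))
                eps2 = rng.normal()
                alpha_i = float(np.clip(
                    cfg.alpha + cfg.alpha_spread * (
                        cfg.rho_div * h + math.sqrt(1 - cfg.rho_div ** 2) * eps2),
                    0.4, 3.0))

                pool = pools[locus]
                members = pool[: n_cluster[locus]]
                background = pool[n_cluster[locus]:]

                # planted members: presence and weight follow the cluster factor
                mem_seqs, mem_weights = [], []
                for seq in members:
                    k = cluster_of[locus][seq]
                    p_in = _sigmoid(logit_pi + cfg.presence_gain * u[k])
                    if rng.random() < p_in:
                        mem_seqs.append(seq)
                        mem_weights.append(float(_softplus(np.array(
                            cfg.lam * u[k] + cfg.sigma_eps * rng.normal()))))

                bg_seqs = [seq for seq in background if rng.random() < cfg.pi_public]
                n_private = max(10, n_target - len(bg_seqs) - len(mem_seqs))
                taken = set(pool)
                private: list[str] = []
                while len(private) < n_private:
                    batch = _sample_many_cdr3(
                        locus, n_private - len(private) + 8, rng,
                        cfg.length_mean[locus], cfg.length_sd[locus], cfg.min_len)
                    for s in batch:
                        if s not in taken and len(private) < n_private:
                            taken.add(s)
                            private.append(s)

                ordinary = bg_seqs + private
                ranks = rng.permutation(len(ordinary)) + 1
                w_ord = ranks.astype(float) ** (-alpha_i)
                scale = float(w_ord.mean()) if len(w_ord) else 1.0
                w = np.concatenate([w_ord, scale * np.array(mem_weights)]) \
                    if mem_weights else w_ord
                seqs = ordinary + mem_seqs
                total_reads = cfg.reads_per_clonotype * len(seqs)
                counts = rng.multinomial(total_reads, w / w.sum())
                keep = counts > 0

                records = []
                for seq, cnt in zip(np.array(seqs)[keep], counts[keep]):
                    subset = None
                    if cfg.annotate_subsets:
                        subset = _assign_subset(str(seq), locus, cluster_of[locus], rng)
                    records.append(ClonotypeRecord(str(seq), int(cnt), locus, subset))
                records.sort(key=lambda r: r.junction_aa)
                cohort.add(Repertoire(indiv, study, condition, locus, records))
    return cohort, gt


def _assign_subset(seq: str, locus: str, cluster_of: dict,
                   rng: np.random.Generator) -> str:
    """Planted cluster members are labeled memory; others random."""
    if locus == "IGH":
        if seq in cluster_of:
            return "memory_B"
        return str(rng.choice(B_SUBSETS))
    if seq in cluster_of:
        return "memory_CD4"
    return str(rng.choice(T_SUBSETS))


def write_cohort(cohort: Cohort, gt: GroundTruth, out_dir: str | Path) -> Path:
    """Write AIRR TSVs per repertoire, a manifest YAML, and ground_truth.json.

    Returns the manifest path, loadable with ``repdata.load_cohort``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for (study, indiv) in cohort.individuals():
        entry = {"study_id": study, "individual_id": indiv,
                 "condition": cohort.condition_of(study, indiv)}
        cov = cohort.covariates.get((study, indiv), {})
        if "q30_fraction" in cov:
            entry["q30_fraction"] = cov["q30_fraction"]
        for locus, key in (("IGH", "igh_path"), ("TRB", "trb_path")):
            rep = cohort.get(study, indiv, locus)
            if rep is None:
                continue
            rel = f"{study}_{indiv}_{locus}.tsv"
            write_airr_repertoire(rep, out / rel)
            entry[key] = rel
        entries.append(entry)
    manifest = out / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"individuals": entries}, fh, sort_keys=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({
            "factors": {f"{s}/{i}": v for (s, i), v in gt.factors.items()},
            "cluster_b_members": gt.cluster_b_members,
            "cluster_t_members": gt.cluster_t_members,
            "motifs": gt.motifs,
        }, fh, indent=1)
    return manifest
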