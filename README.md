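# crossrep

Cross-receptor analysis of paired adaptive immune repertoires: do an
individual's B-cell (IGH) and T-cell (TRB) CDR3 repertoires co-vary, and do
specific groups of public B and T clonotypes rise and fall together?

`crossrep` is a Python library (with a thin `crossrep` CLI) for scientists
working with AIRR-seq clonotype tables from multi-study cohorts. It
implements a complete pipeline:

1. **Clonality & diversity statistics** per repertoire: clonal volume,
   top-100 / hyperexpanded (> 1% of clonal space) / small (< 0.001%) / rare
   (count < 3) clone proportions, Chao1, Hill numbers ¹D = exp(H_Shannon)
   and ²D = 1/Σp²ᵢ, Gini–Simpson 1 − Σp²ᵢ, and the Gini coefficient — with
   read- or clonotype-level downsampling to fixed repertoire sizes.
2. **CDR3 similarity networks**: unweighted graphs connecting clonotypes
   within Levenshtein distance 3, summarized by degree assortativity,
   average degree, average clustering, density, and local/global efficiency.
3. **Cross-receptor correlation meta-analysis**: per-study Spearman ρ
   between paired B and T statistics, pooled on the Fisher-z scale with a
   common-effect inverse-variance model (z_k = atanh r_k, var_k =
   1/(n_k − 3)), BH FDR across the metric family.
4. **Public-clonotype B×T clustering**: clonal-proportion matrices over
   public clonotypes (found in ≥ 2 individuals; absent = 0), per-study
   Pearson correlation of every B×T clonotype pair pooled by the same
   meta-analysis, and hierarchical clustering of the pooled matrix into
   correlated B×T blocks. A cell-subset variant correlates the top-50
   public clonotypes of each annotated subset.
5. **Cluster characterization**: mean pairwise Levenshtein distance and
   per-residue physicochemical averages (Kidera factors 1–10, charge, core,
   disorder, MJ energy, hydropathy, volume, polarity) versus 10,000 random
   size-matched public groups (KS tests), plus exhaustive discrete motif
   enrichment (Fisher exact on per-sequence presence; ratio
   (k_in/n_in)/(k_out/n_out)).
6. **Antigen annotation**: exact CDR3β matching against McPAS-TCR/VDJdb-style
   exports with per-category fold enrichment.
7. **Replication**: in an independent cohort, per-individual cluster match
   fractions Fr_B (within 2 edits) and Fr_T (exact) feed the regression
   Fr_T ~ Fr_B + C (C = total clonotype count), calibrated against 100
   refits on random clusters of matched sizes (add-one empirical p).
8. **Synthetic cohorts**: a generator that plants all of the above —
   shared latent size/diversity factors, heavy-tailed Zipf abundances,
   public pools, correlated B×T clusters with mutually similar,
   motif-bearing sequences — with full ground truth for recovery testing.

## Worked example

```python
from crossrep import SynthConfig, generate_cohort, clonstats, metacorr

cohort, truth = generate_cohort(SynthConfig(seed=11))
table = clonstats.summarize_cohort(cohort)
for res in metacorr.correlate_paired_metrics(
        table, "healthy", ["clonal_volume", "chao1", "hill_q1", "gini"]):
    print(res.metric, round(res.r, 3), f"q={res.q:.2e}")
```

prints

```
clonal_volume 0.434 q=4.56e-06
chao1 0.426 q=4.56e-06
hill_q1 0.381 q=4.07e-05
gini 0.366 q=6.82e-05
```

i.e. across 4 simulated studies, individuals with larger and more diverse
B-cell repertoires also have larger and more diverse T-cell repertoires
(pooled Spearman r ≈ 0.37–0.43, all FDR-significant), as planted by the
generator's shared size factor. Continuing with
`examples/04_cluster_discovery.py` and `examples/05_replication.py`
recovers the three planted 10 B × 20 T clusters (mean block |r| ≈ 0.6–0.7,
mean pairwise LD ≈ 2 vs ≈ 14 for random public groups, planted motifs
reported) and replicates them in an independent cohort (slope 0.46,
empirical p = 1/101 ≈ 0.0099). The `examples/` directory has one short
script per capability.

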