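# Methods

## Scope and model

`crossrep` asks whether adaptive immunity is coordinated across receptor
arms: whether summary statistics of an individual's B-cell (IGH) and T-cell
(TRB) CDR3 repertoires correlate across individuals, and whether specific
public B and T clonotypes form clusters whose clonal proportions co-vary.
Clonotypes are keyed on the CDR3 amino-acid string alone; identical CDR3s
with different V/J annotations are merged. This matches the definition of a
public clonotype (same CDR3 in ≥ 2 individuals) used throughout; the
alternative (keying on V–CDR3–J) would fragment public sharing and is not
implemented.

## Summary statistics

All indices operate on clonal proportions p_i = count_i / Σcounts.

- Clone-size bins: hyperexpanded = proportion > 1% of clonal space, small =
  proportion < 0.001%, rare = absolute count < 3, top-100 = cumulative
  proportion of the 100 most abundant clonotypes. The hyperexpanded/small
  thresholds are proportions of clonal space (reads), not of the clonotype
  count — both are configurable (`BinThresholds`). Top-N boundary ties are
  broken lexicographically for determinism.
- Chao1 (bias-corrected by default): S + F1(F1−1)/(2(F2+1)); the classic
  S + F1²/(2F2) is available and falls back to the corrected form when
  F2 = 0.
- Hill numbers with natural-log Shannon entropy, so the identity
  gini_simpson = 1 − 1/²D is exact (asserted to 1e-12 in tests).
- Gini coefficient via the sorted O(n log n) formula, equal to
  ΣΣ|x_i − x_j| / (2n²x̄).

Downsampling to fixed sizes (a sequencing-depth sensitivity analysis) is
hypergeometric over reads for clonality/diversity (preserves expected
proportions) and uniform over unique clonotypes for networks (frequency
information removed before graph construction). Repertoires smaller than a
requested size are skipped with a flag, not an error.

## Similarity networks

Nodes are unique CDR3s; edges connect pairs with 1 ≤ LD ≤ 3 (identical
sequences cannot co-occur as distinct nodes). Distances come from edlib
(banded, with exact length-difference pruning); a textbook DP implementation
serves as the test oracle. Metrics are computed with networkx; tests verify
all six against an independent brute-force implementation (scipy shortest
paths, explicit triangle counts, Pearson over edge-endpoint degrees) to
1e-9 on 200+-node graphs. Conventions: 1/∞ = 0 for disconnected pairs,
clustering and local efficiency are 0 for degree < 2 nodes, degree
assortativity is NaN on degree-regular graphs and such values are excluded
downstream.

## Correlation meta-analysis

Per study, Spearman's ρ (mid-rank ties, t-approximation p) over paired
individuals; studies need ≥ 4 complete pairs. Pooling is a common-effect
inverse-variance model on the Fisher-z scale with var_k = 1/(n_k − 3) —
the classical ZCOR estimator — with two-sided normal p and back-transformed
CI. Tests cross-check the pooled estimate against statsmodels
`combine_effects` and a hand-computed two-study example. |r| = 1 is clipped
to 0.999999 before atanh. BH FDR is applied per metric family within one
condition group (the family is the list of metrics passed in one call;
callers may partition differently). The Q30 covariate analysis is plain OLS
y ~ 1 + x + cov with a collinearity flag.

## Public-clonotype clustering

Proportion matrices place individuals in rows and public clonotypes in
columns; an absent clonotype is an exact 0, because absence is informative
for co-occurrence. Every B×T column pair is correlated with Pearson's r per
study (following the explicit choice of Pearson for clonotype-proportion
correlations; configurable in principle via the matrices handed in),
requiring ≥ 4 individuals and non-zero variance in both columns for a study
to contribute; per-study r is pooled exactly as above. Pairs estimable in
no study are NaN and imputed as 0 before clustering.

Cluster extraction replaces the visual heatmap selection of the original
workflow with an explicit, reproducible criterion: rows (B) and columns (T)
are hierarchically clustered (complete linkage, Euclidean distance on
correlation profiles — the defaults of the R tools the workflow emulates),
trees are cut at a fixed count or, by default, at 0.5 × the final merge
height, and every B-group × T-group block is scored by mean |pooled r|.
Blocks with score ≥ 0.4 and ≥ 2 members per side are emitted best-first,
each group joining at most one emitted pair. Block scoring uses |r| (not
r²) since sign carries information. The fraction of public clonotypes
assigned to clusters is reported, never asserted — it is data-dependent.

The cell-subset analysis ranks the top-50 public clonotypes per annotated
subset by pooled within-subset counts, correlates all selected pairs over
common individuals, counts pairs with r above a threshold (no silent
default; 0.7 in the CLI, matching the reported analyses) and p < 0.05 per
subset-pair category, and compares a focal category against its complement
with Fisher's exact test.

## Sequence features, nulls, and motifs

Cluster similarity = mean pairwise LD; physicochemical profile = unweighted
mean over sequences of per-residue means. Property scales are bundled and
checksummed: the canonical Kidera factors, Kyte–Doolittle hydropathy,
Zamyatnin volumes, Grantham polarity, TOP-IDP disorder, Miyazawa–Jernigan
self-contact energies, Janin interior propensity, and integer side-chain
charge (H neutral). Null distributions are built from 10,000 uniform
size-matched groups of public clonotypes; pairwise distances and property
values are precomputed over the pool once, so the 10,000 group averages are
indexed means. Observed-vs-null comparisons use the two-sample KS test.

Motif discovery is an exhaustive scan of contiguous substrings (widths
3–10) present in ≥ 2 in-group sequences, tested by one-sided Fisher exact
on per-sequence presence (a sequence counts once however often the motif
recurs, matching the x/n presentation of motif tables). The enrichment
ratio is (k_in/n_in)/(k_out/n_out), reported as NA when the motif never
occurs outside the group. The BH family spans *all* enumerated patterns
(patterns below the support filter enter with p = 1): correcting only over
supported candidates would let chance two-sequence collisions with a clean
out-group pass at any α, because the support filter is itself selection on
the data. Reported motifs are de-duplicated: a motif contained in an
already-reported, at-least-as-significant longer motif is suppressed. This
replaces PWM-based discovery (STREME) with a deterministic, exactly
testable procedure; it finds fixed planted motifs but not degenerate ones.

## Antigen annotation

Exact CDR3β string matching against a (cdr3, category) table (McPAS-TCR and
VDJdb slim export dialects supported). Enrichment per category is
f_cluster/f_background; a clonotype may match several categories, so
ratios are unconstrained across categories. Fuzzy matching is deliberately
excluded to keep the statistic deterministic.

## Replication

Fr^m_i is the fraction of cluster m's members that individual i carries —
within 2 edits for B members (exact matches of clustered B clonotypes are
rare), exact for T. Records over all clusters and individuals feed one
pooled OLS Fr_T ~ 1 + Fr_B + C, where C is the individual's combined unique
B+T clonotype count; per-cluster fits are available as a diagnostic, and
standard errors are plain OLS (a cluster-robust option would be a
conservative extension; records within an individual are correlated).
Significance is calibrated by refitting on 100 random same-size clusters
drawn from the public pools; the empirical p uses the add-one rule
(1 + #{|slope₀| ≥ |slope|})/(n+1), so a slope exceeding every null gives
1/101 ≈ 0.0099. Match indicators are precomputed as an individuals × pool
matrix so observed and null regressions share one code path.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes — it
makes no claim to biophysical realism (no V(D)J recombination, hypermutation
or germline usage; private CDR3s are uniform random strings with C/F-W
anchors and normally distributed lengths).

Per individual: latent g, h ~ N(0,1) shared between chains; log repertoire
size = μ_locus + σ(ρ_size·g + √(1−ρ_size²)ε); Zipf abundance exponent
α_i = α + 0.3(ρ_div·h + √(1−ρ_div²)ε′) clipped to [0.4, 3]; counts are a
multinomial draw (10 reads per clonotype on average) over Zipf rank
weights, dropping zero-count clonotypes. Background public-pool members are
included with probability π. For cluster k with factor u_{i,k} ~ N(0,1):
member presence has probability sigmoid(logit π + 2u_{i,k}) and member
weight softplus(λu_{i,k} + σ_ε ε) scaled to a typical clonotype weight —
presence modulation is essential, since with constant presence the
replication fractions would be nearly constant and the Fr regression
degenerate. Cluster member sequences are substitution-only variants (≤
d_intra edits) of a per-cluster seed carrying a planted motif at a fixed
interior offset, so within-cluster LD ≤ 2·d_intra; memberships are disjoint.
One RNG stream per individual is derived by SHA-based stable hashing of
(seed, replicate, study, individual): outputs are byte-identical across
runs and independent of generation order, and `replicate > 0` yields new
individuals with identical pools/clusters/motifs for replication analyses.

Default study conditions (chosen once as a desk-scale analogue of a
multi-study cohort): 4 studies × 30 individuals, mean volumes ~250 IGH /
~500 TRB (σ = 0.4 on the log scale), ρ_size = 0.7, ρ_div = 0.5, pools
P_B = 150 / P_T = 300 with π = 0.5, K = 3 clusters of 10 B × 20 T with
λ = 2.0, σ_ε = 0.5, d_intra = 2, motifs WGQG/YEQY/HNDW; replication cohort
1 study × 50 individuals. With these settings the pooled clonal-volume
correlation lands around 0.3–0.5 — the order of magnitude reported for real
cohorts — rising to ~0.55–0.75 at ρ_size = 0.9 and vanishing at ρ_size = 0.

What passing recovery tests does and does not show: the pipeline detects
exactly the structure the generator plants (co-varying proportions,
convergent sequences, discrete motifs). Real repertoires add germline-driven
sharing, length/composition biases, sequencing-depth artifacts and batch
effects that the generator does not model, so recovery here demonstrates
correctness of the machinery, not expected effect sizes in real data.

## Numerical and degenerate-input conventions

Proportions must sum to 1 within 1e-9; metrics on empty repertoires raise;
constant vectors yield flagged NaNs rather than exceptions wherever a
cohort-level analysis should continue; downsampling sizes above the
repertoire are skipped with a warning; Fisher-z clips |r| = 1; correlation
ties break deterministically (lexicographic CDR3 order). All stochastic
steps accept explicit seeds or generators.

## Known limitations

- Clustering cut parameters (height fraction, block score threshold) are
  explicit but still tuning knobs; very weak or overlapping clusters will
  not separate, and the spurious small blocks that pass the score threshold
  in noisy matrices are left to the replication stage to reject.
- The motif scanner cannot find gapped or degenerate motifs.
- Spearman p-values use the t approximation (adequate for n ≥ ~5, the
  smallest per-study samples accepted).
- The Fr regression treats records as independent although individuals
  contribute one record per cluster.
- Property-scale values for core/disorder/MJ energy are literature scales
  standing behind the conventional property names; analyses using them are
  relative (cluster vs null), so scale provenance does not affect
  conclusions.
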