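"""CDR3 similarity networks and their six global metrics.

Each repertoire is downsampled to fixed numbers of unique clonotypes
(frequency information removed), sequences become nodes, and edges connect
clonotypes within Levenshtein distance 3.
"""

from crossrep import SynthConfig, generate_cohort, repnet

cohort, _ = generate_cohort(SynthConfig(n_studies=1, individuals_per_study=2,
                                        seed=11))
rep = next(cohort.iter_repertoires(locus="TRB"))
table = repnet.network_summary(rep, sizes=(100, 200), seed=0)
cols = ["size"] + repnet.METRIC_NAMES
print(table[cols].round(4).to_string(index=False))
# Density and average degree measure how many clonotype pairs are within 3
# edits; clustering and local efficiency describe tightly knit sequence
# neighborhoods; global efficiency summarizes how connected the whole
# repertoire is (disconnected pairs contribute 0).
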