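"""Annotate clustered T clonotypes with known antigen specificities.

A toy antigen table (the export shape of McPAS-TCR / VDJdb: CDR3beta +
antigen category) is built so that one category is over-represented in a
"cluster" relative to the background public pool; fold enrichment is the
ratio of in-cluster to background match fractions.
"""

import numpy as np

from crossrep.antigendb import AntigenDB, cluster_antigen_enrichment

rng = np.random.default_rng(0)
AA = list("ACDEFGHIKLMNPQRSTVWY")
background = {"C" + "".join(rng.choice(AA, size=11)) + "F" for _ in range(500)}
background = sorted(background)
cluster = set(background[:50])

db = AntigenDB()
for s in background[:10]:                     # 20% of the cluster
    db.records.add((s, "SARS-CoV-2"))
for s in background[50:70]:                   # ~4% of the rest
    db.records.add((s, "SARS-CoV-2"))
for s in background[70:85]:
    db.records.add((s, "CMV"))

table = cluster_antigen_enrichment(cluster, set(background), db)
print(table.round(3).to_string(index=False))
# enrichment > 1: the cluster contains proportionally more clonotypes with
# that known specificity than the public background; here the SARS-CoV-2
# rate in the cluster (10/50) is ~3x the background rate (30/500).
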