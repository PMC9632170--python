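import numpy as np
import pytest

from crossrep.repdata import ClonotypeRecord, Repertoire

AA = "ACDEFGHIKLMNPQRSTVWY"


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def random_cdr3(rng: np.random.Generator, length: int = 12) -> str:
    mid = "".join(rng.choice(list(AA), size=length - 2))
    return "C" + mid + "F"


def make_repertoire(counts, seqs=None, locus="TRB", individual_id="ind1",
                    study_id="study1", condition="healthy", subsets=None):
    """Build a repertoire from counts, inventing distinct sequences if needed."""
    rng = np.random.default_rng(12345)
    if seqs is None:
        seqs = set()
        while len(seqs) < len(counts):
            seqs.add(random_cdr3(rng))
        seqs = sorted(seqs)
    records = [
        ClonotypeRecord(s, int(c), locus,
                        subsets[i] if subsets is not None else None)
        for i, (s, c) in enumerate(zip(seqs, counts))
    ]
    return Repertoire(individual_id, study_id, condition, locus, records)


@pytest.fixture
def toy_repertoire():
    return make_repertoire([5, 3, 2])


@pytest.fixture(scope="session")
def small_cohort():
    """A small generated cohort with planted structure, shared across tests."""
    from crossrep.synthdata import SynthConfig, generate_cohort
    cfg = SynthConfig(n_studies=2, individuals_per_study=20, P_B=60, P_T=90,
                      K=2, n_b_per_cluster=6, n_t_per_cluster=8, seed=7)
    return generate_cohort(cfg)
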