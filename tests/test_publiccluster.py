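import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossrep import publiccluster as pc
from crossrep.repdata import Cohort
from crossrep.synthdata import SynthConfig, generate_cohort

from conftest import make_repertoire, random_cdr3


def _toy_cohort():
    """Four paired individuals; sequence X shared by two, Y private to one."""
    cohort = Cohort()
    base = ["CAAAAF", "CDDDDF", "CGGGGF", "CHHHHF"]
    shared = "CSHAREDF"
    lone = "CLNEF"
    letters = "ACDE"
    for k in range(4):
        seqs_b = [f"C{letters[k]}WAAF", f"C{letters[k]}WCCF"]
        cohort.add(make_repertoire([3, 2], seqs=sorted(seqs_b), locus="IGH",
                                   individual_id=f"i{k}"))
        seqs_t = [base[k], shared] if k < 2 else [base[k], lone if k == 2 else "CEEEEF"]
        order = np.argsort(seqs_t)
        cohort.add(make_repertoire([int(c) for c in np.array([5, 5])[order]],
                                   seqs=sorted(seqs_t), locus="TRB",
                                   individual_id=f"i{k}"))
    return cohort, shared, lone


class TestFindPublic:
    def test_shared_in_two_is_public_lone_is_not(self):
        cohort, shared, lone = _toy_cohort()
        pub = pc.find_public_clonotypes(cohort, "TRB", "healthy")
        assert shared in pub
        assert lone not in pub

    def test_planted_members_recovered(self, small_cohort):
        cohort, gt = small_cohort
        pub = pc.find_public_clonotypes(cohort, "TRB", "healthy")
        planted = {s for g in gt.cluster_t_members for s in g}
        # planted members present in >= 2 individuals must be detected
        carriers = {}
        for rep in cohort.iter_repertoires(locus="TRB", condition="healthy"):
            for s in set(rep.sequences) & planted:
                carriers[s] = carriers.get(s, 0) + 1
        expected = {s for s, n in carriers.items() if n >= 2}
        assert expected <= pub


class TestProportionMatrix:
    def test_entries_and_absences(self):
        cohort, shared, _ = _toy_cohort()
        mat = pc.proportion_matrix(cohort, {shared}, "TRB", "healthy")
        col = mat[shared]
        assert sorted(col.values) == pytest.approx([0.0, 0.0, 0.5, 0.5])

    def test_column_occupancy_matches_publicity(self, small_cohort):
        cohort, _ = small_cohort
        pub = pc.find_public_clonotypes(cohort, "IGH", "healthy")
        mat = pc.proportion_matrix(cohort, pub, "IGH", "healthy")
        assert ((mat > 0).sum(axis=0) >= 2).all()

    def test_rows_sum_below_one(self, small_cohort):
        cohort, _ = small_cohort
        pub = pc.find_public_clonotypes(cohort, "TRB", "healthy")
        mat = pc.proportion_matrix(cohort, pub, "TRB", "healthy")
        assert (mat.values.sum(axis=1) <= 1 + 1e-9).all()


class TestTopPublicBySubset:
    def _subset_cohort(self):
        cohort = Cohort()
        seqs = ["CAAF", "CDDF", "CGGF"]
        for k, counts in enumerate(([10, 7, 1], [10, 7, 1])):
            cohort.add(make_repertoire(counts, seqs=seqs, locus="TRB",
                                       individual_id=f"i{k}",
                                       subsets=["memory_CD4"] * 3))
            cohort.add(make_repertoire([1], seqs=["CHHF"], locus="IGH",
                                       individual_id=f"i{k}",
                                       subsets=["naive_B"]))
        return cohort

    def test_ranked_by_pooled_count(self):
        cohort = self._subset_cohort()
        top = pc.top_public_by_subset(cohort, "memory_CD4", k=2)
        assert top == ["CAAF", "CDDF"]

    def test_k_exceeding_pool_returns_all(self):
        cohort = self._subset_cohort()
        top = pc.top_public_by_subset(cohort, "memory_CD4", k=50)
        assert top == ["CAAF", "CDDF", "CGGF"]

    def test_absent_subset_errors(self):
        cohort = self._subset_cohort()
        with pytest.raises(ValueError):
            pc.top_public_by_subset(cohort, "memory_B")


class TestCountHighCorrelations:
    def _matrices(self, rng, n=12, planted=False):
        idx = pd.MultiIndex.from_tuples([("s1", f"i{k}") for k in range(n)],
                                        names=["study_id", "individual_id"])
        a = pd.DataFrame(rng.uniform(size=(n, 5)),
                         columns=[f"CA{j}F" for j in range(5)], index=idx)
        b = pd.DataFrame(rng.uniform(size=(n, 5)),
                         columns=[f"CB{j}F" for j in range(5)], index=idx)
        if planted:
            shared = rng.normal(size=n)
            for j in range(5):
                a.iloc[:, j] = shared + 0.05 * rng.normal(size=n)
        return {"memory_CD4": a, "naive_CD4": b}

    def test_independent_columns_no_high_pairs(self):
        mats = self._matrices(np.random.default_rng(0))
        out = pc.count_high_correlations(mats, r_thresh=0.95, p_thresh=1e-6)
        assert (out["n_high"] == 0).all()

    def test_fisher_matches_hypergeometric_oracle(self):
        table = [[10, 90], [1, 99]]
        _, p = stats.fisher_exact(table)
        # brute-force: sum hypergeometric probabilities <= observed
        M, n, N = 200, 11, 100
        probs = [stats.hypergeom.pmf(k, M, n, N) for k in range(12)]
        p_obs = stats.hypergeom.pmf(10, M, n, N)
        oracle = sum(q for q in probs if q <= p_obs * (1 + 1e-9))
        assert p == pytest.approx(oracle, abs=1e-10)

    def test_planted_memory_block_detected(self):
        hits = 0
        for seed in range(10):
            mats = self._matrices(np.random.default_rng(seed), planted=True)
            out = pc.count_high_correlations(mats, r_thresh=0.8,
                                             focal=("memory_CD4", "memory_CD4"))
            frac = out.set_index(["subset_a", "subset_b"])
            f_mem = frac.loc[("memory_CD4", "memory_CD4"), "fraction"]
            others = frac.drop(("memory_CD4", "memory_CD4"))["fraction"]
            if f_mem > others.max() and out.attrs["fisher_p_greater"] < 0.05:
                hits += 1
        assert hits >= 9


class TestPairwiseBtCorrelations:
    def _idx(self, study, n):
        return pd.MultiIndex.from_tuples([(study, f"i{k}") for k in range(n)],
                                         names=["study_id", "individual_id"])

    def test_proportional_columns_give_r_one(self):
        rng = np.random.default_rng(1)
        idx = self._idx("s1", 10)
        b = pd.DataFrame({"CBF": rng.uniform(size=10)}, index=idx)
        t = pd.DataFrame({"CTF": 2.0 * b["CBF"].values}, index=idx)
        R, k = pc.pairwise_bt_correlations(b, t)
        assert R.loc["CBF", "CTF"] == pytest.approx(1.0, abs=1e-4)
        assert k.loc["CBF", "CTF"] == 1

    def test_independent_columns_small_r(self):
        count = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            idx = self._idx("s1", 40)
            b = pd.DataFrame({"CBF": rng.uniform(size=40)}, index=idx)
            t = pd.DataFrame({"CTF": rng.uniform(size=40)}, index=idx)
            R, _ = pc.pairwise_bt_correlations(b, t)
            if abs(R.loc["CBF", "CTF"]) < 0.5:
                count += 1
        assert count >= 19

    def test_cardinality_and_zero_variance_nan(self):
        rng = np.random.default_rng(2)
        idx = self._idx("s1", 8)
        b = pd.DataFrame(rng.uniform(size=(8, 10)),
                         columns=[f"CB{j}F" for j in range(10)], index=idx)
        t = pd.DataFrame(rng.uniform(size=(8, 20)),
                         columns=[f"CT{j}F" for j in range(20)], index=idx)
        t["CT0F"] = 0.0  # constant column: inestimable
        R, _ = pc.pairwise_bt_correlations(b, t)
        assert R.shape == (10, 20)
        assert R["CT0F"].isna().all()
        assert R.drop(columns="CT0F").notna().all().all()

    def test_multi_study_pooling_matches_manual(self):
        rng = np.random.default_rng(3)
        frames_b, frames_t = [], []
        manual = []
        for s, n in (("s1", 10), ("s2", 14)):
            idx = self._idx(s, n)
            xb = rng.uniform(size=n)
            xt = xb + rng.normal(scale=0.4, size=n)
            frames_b.append(pd.DataFrame({"CBF": xb}, index=idx))
            frames_t.append(pd.DataFrame({"CTF": xt}, index=idx))
            manual.append((np.corrcoef(xb, xt)[0, 1], n))
        R, _ = pc.pairwise_bt_correlations(pd.concat(frames_b),
                                           pd.concat(frames_t))
        num = sum((n - 3) * np.arctanh(r) for r, n in manual)
        den = sum(n - 3 for _, n in manual)
        assert R.loc["CBF", "CTF"] == pytest.approx(np.tanh(num / den), abs=1e-9)


class TestClusterCorrelationMatrix:
    def _block_matrix(self, rng, r_in=0.9, b=(4, 4), t=(5, 5), noise=0.0):
        nb, nt = sum(b), sum(t)
        R = noise * rng.normal(size=(nb, nt))
        R[: b[0], : t[0]] = r_in
        R[b[0]:, t[0]:] = r_in
        return pd.DataFrame(R, index=[f"CB{i}F" for i in range(nb)],
                            columns=[f"CT{j}F" for j in range(nt)])

    def test_planted_blocks_recovered_exactly(self):
        R = self._block_matrix(np.random.default_rng(0))
        pairs = pc.cluster_correlation_matrix(R, min_mean_abs_r=0.5)
        assert len(pairs) == 2
        members = sorted((sorted(p.b_members), sorted(p.t_members))
                         for p in pairs)
        assert members[0] == ([f"CB{i}F" for i in range(4)],
                              [f"CT{j}F" for j in range(5)])
        assert members[1] == ([f"CB{i}F" for i in range(4, 8)],
                              [f"CT{j}F" for j in range(5, 10)])

    def test_all_zero_matrix_no_clusters(self):
        R = pd.DataFrame(np.zeros((6, 6)),
                         index=[f"CB{i}F" for i in range(6)],
                         columns=[f"CT{j}F" for j in range(6)])
        assert pc.cluster_correlation_matrix(R) == []

    def test_permutation_invariant(self):
        rng = np.random.default_rng(4)
        R = self._block_matrix(rng, noise=0.05)
        perm = R.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2)
        p1 = pc.cluster_correlation_matrix(R, min_mean_abs_r=0.5)
        p2 = pc.cluster_correlation_matrix(perm, min_mean_abs_r=0.5)
        sets1 = sorted((frozenset(p.b_members), frozenset(p.t_members))
                       for p in p1)
        sets2 = sorted((frozenset(p.b_members), frozenset(p.t_members))
                       for p in p2)
        assert sets1 == sets2

    def test_degenerate_matrix_rejected(self):
        R = pd.DataFrame(np.ones((1, 5)), index=["CBF"],
                         columns=[f"CT{j}F" for j in range(5)])
        with pytest.raises(ValueError):
            pc.cluster_correlation_matrix(R)


class TestSampleRandomGroups:
    def test_full_pool_groups(self):
        groups = pc.sample_random_groups({"A", "B", "C"}, 3, n_iter=5,
                                         rng=np.random.default_rng(0))
        assert all(sorted(g) == ["A", "B", "C"] for g in groups)

    def test_seeded_reproducibility(self):
        pool = [f"CS{i}F" for i in range(30)]
        g1 = pc.sample_random_groups(pool, 5, 50, np.random.default_rng(9))
        g2 = pc.sample_random_groups(pool, 5, 50, np.random.default_rng(9))
        assert g1 == g2

    def test_oversized_group_rejected(self):
        with pytest.raises(ValueError):
            pc.sample_random_groups({"A"}, 2, 10)

    def test_group_means_consistent_with_pool_mean(self):
        rng = np.random.default_rng(10)
        pool = sorted({random_cdr3(rng, int(rng.integers(8, 16))) for _ in range(40)})
        vals = {s: len(s) for s in pool}
        groups = pc.sample_random_groups(set(pool), 8, 2000, rng)
        means = [np.mean([vals[s] for s in g]) for g in groups]
        pool_mean = np.mean([vals[s] for s in set(pool)])
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - pool_mean) < 3 * se + 1e-9


class TestRecoveryEndToEnd:
    def test_planted_cluster_recovery_ari(self, small_cohort):
        from sklearn.metrics import adjusted_rand_score
        cohort, gt = small_cohort
        pub_b = pc.find_public_clonotypes(cohort, "IGH", "healthy")
        pub_t = pc.find_public_clonotypes(cohort, "TRB", "healthy")
        bmat = pc.proportion_matrix(cohort, pub_b, "IGH", "healthy")
        tmat = pc.proportion_matrix(cohort, pub_t, "TRB", "healthy")
        R, _ = pc.pairwise_bt_correlations(bmat, tmat)
        pairs = pc.cluster_correlation_matrix(R)
        for locus in ("IGH", "TRB"):
            planted = gt.membership(locus)
            rec = {}
            for p in pairs:
                for s in (p.b_members if locus == "IGH" else p.t_members):
                    rec[s] = p.cluster_id
            seqs = sorted(planted)
            ari = adjusted_rand_score([planted[s] for s in seqs],
                                      [rec.get(s, -1) for s in seqs])
            assert ari >= 0.7
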