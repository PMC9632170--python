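import numpy as np
import pytest

from crossrep import seqfeat
from crossrep.seqfeat import (DEFAULT_PROPERTIES, PropertyTable,
                              group_property_mean, ks_two_sample,
                              mean_pairwise_ld, motif_enrichment,
                              null_feature_distribution, scan_motifs,
                              sequence_property_mean)

from conftest import dp_levenshtein, random_cdr3


class TestMeanPairwiseLd:
    def test_hand_value_three_sequences(self):
        assert mean_pairwise_ld({"AAA", "AAB", "ABB"}) == pytest.approx(4 / 3)

    def test_two_distant_sequences(self):
        assert mean_pairwise_ld(["CAAAAF", "CTTTTTTF"]) == pytest.approx(
            dp_levenshtein("CAAAAF", "CTTTTTTF"))

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(0)
        group = sorted({random_cdr3(rng, int(rng.integers(8, 16)))
                        for _ in range(100)})
        total, n = 0, 0
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                total += dp_levenshtein(a, b)
                n += 1
        assert mean_pairwise_ld(group) == pytest.approx(total / n, abs=1e-12)

    def test_permutation_invariant(self):
        group = ["CAAF", "CDDF", "CWWF"]
        assert mean_pairwise_ld(group) == mean_pairwise_ld(group[::-1])

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            mean_pairwise_ld(["CAAF"])


class TestPropertyMeans:
    def test_homopolymer_returns_table_value(self):
        table = DEFAULT_PROPERTIES
        assert sequence_property_mean("AAAA", "hydropathy", table) == \
            pytest.approx(table.values["hydropathy"]["A"])

    def test_two_residue_average(self):
        table = DEFAULT_PROPERTIES
        want = (table.values["KF1"]["A"] + table.values["KF1"]["D"]) / 2
        assert sequence_property_mean("ADAD", "KF1", table) == pytest.approx(want)

    def test_residue_order_invariant(self):
        assert sequence_property_mean("CASSF", "volume") == \
            pytest.approx(sequence_property_mean("FSSAC", "volume"))

    def test_group_mean_identical_sequences(self):
        v = sequence_property_mean("CASSF", "charge")
        assert group_property_mean(["CASSF", "CASSF"], "charge") == pytest.approx(v)

    def test_group_mean_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        group = [random_cdr3(rng, 12) for _ in range(50)]
        table = DEFAULT_PROPERTIES
        oracle = np.mean([np.mean([table.values["polarity"][aa] for aa in s])
                          for s in group])
        assert group_property_mean(group, "polarity") == pytest.approx(oracle)

    def test_all_twenty_residues_covered(self):
        table = PropertyTable()
        for prop, scale in table.values.items():
            assert sorted(scale) == sorted("ACDEFGHIKLMNPQRSTVWY"), prop

    def test_unknown_property_rejected(self):
        with pytest.raises(KeyError):
            sequence_property_mean("CASSF", "no_such_scale")

    def test_checksum_stable(self):
        assert PropertyTable().checksum() == DEFAULT_PROPERTIES.checksum()


class TestNullDistribution:
    def test_spread_and_reproducibility(self):
        rng = np.random.default_rng(2)
        pool = sorted({random_cdr3(rng, 12) for _ in range(60)})
        n1 = null_feature_distribution(pool, 6, n_iter=300,
                                       rng=np.random.default_rng(5))
        n2 = null_feature_distribution(pool, 6, n_iter=300,
                                       rng=np.random.default_rng(5))
        assert n1.samples["mean_pairwise_ld"].std() > 0
        assert n1.samples.equals(n2.samples)

    def test_null_mean_matches_pool_mean(self):
        rng = np.random.default_rng(3)
        pool = sorted({random_cdr3(rng, int(rng.integers(9, 15)))
                       for _ in range(50)})
        null = null_feature_distribution(pool, 8, n_iter=2000,
                                         rng=np.random.default_rng(1))
        pool_mean = np.mean([sequence_property_mean(s, "volume") for s in pool])
        vals = null.samples["volume"]
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - pool_mean) < 3 * se + 1e-9

    def test_ld_cache_reused(self):
        rng = np.random.default_rng(4)
        pool = sorted({random_cdr3(rng, 10) for _ in range(30)})
        cache = {}
        n1 = null_feature_distribution(pool, 5, 100, rng=np.random.default_rng(0),
                                       _ld_cache=cache)
        assert len(cache) == 1
        n2 = null_feature_distribution(pool, 5, 100, rng=np.random.default_rng(0),
                                       _ld_cache=cache)
        assert n1.samples.equals(n2.samples)


class TestKs:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == pytest.approx(1.0)


class TestMotifEnrichment:
    @pytest.mark.parametrize("k_in,n_in,k_out,n_out,want", [
        (42, 455, 126, 24031, 17.61),
        (12, 536, 2, 23950, 268.10),
        (11, 320, 56, 24166, 14.83),
        (9, 323, 13, 33103, 70.95),
        (47, 53, 175, 5453, 27.63),
    ])
    def test_enrichment_ratio_arithmetic(self, k_in, n_in, k_out, n_out, want):
        hit = motif_enrichment(k_in, n_in, k_out, n_out)
        assert hit.enrichment_ratio == pytest.approx(want, abs=0.005)

    @pytest.mark.parametrize("k_in,n_in,k_out,n_out", [
        (11, 316, 0, 24170), (13, 44, 0, 2118),
        (5, 21, 0, 2141), (4, 54, 0, 33368),
    ])
    def test_never_outside_group_is_na(self, k_in, n_in, k_out, n_out):
        hit = motif_enrichment(k_in, n_in, k_out, n_out)
        assert np.isnan(hit.enrichment_ratio)
        assert hit.p < 0.05

    def test_fisher_p_matches_scipy_direct(self):
        from scipy.stats import fisher_exact
        hit = motif_enrichment(8, 20, 10, 200)
        _, p = fisher_exact([[8, 12], [10, 190]], alternative="greater")
        assert hit.p == pytest.approx(p, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment(5, 0, 1, 10)
        with pytest.raises(ValueError):
            motif_enrichment(5, 4, 1, 10)


class TestScanMotifs:
    def test_planted_motif_found(self):
        rng = np.random.default_rng(6)
        in_group = []
        for _ in range(10):
            s = random_cdr3(rng, 13)
            in_group.append(s[:4] + "WGQ" + s[7:])
        out_group = [random_cdr3(rng, 13) for _ in range(100)]
        out_group = [s for s in out_group if "WGQ" not in s]
        hits = scan_motifs(in_group, out_group)
        found = {h.pattern for h in hits}
        assert any("WGQ" in pat for pat in found)
        top = [h for h in hits if "WGQ" in h.pattern][0]
        assert np.isnan(top.enrichment_ratio)  # k_out = 0
        assert top.p < 1e-6

    def test_null_scan_mostly_empty(self):
        empties = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            pool = [random_cdr3(rng, 13) for _ in range(120)]
            in_group, out_group = pool[:12], pool[12:]
            if not scan_motifs(in_group, out_group):
                empties += 1
        assert empties >= 9

    def test_contained_motif_suppressed(self):
        rng = np.random.default_rng(8)
        in_group = []
        for _ in range(12):
            s = random_cdr3(rng, 14)
            in_group.append(s[:4] + "WGQGY" + s[9:])
        out_group = [random_cdr3(rng, 14) for _ in range(150)]
        out_group = [s for s in out_group if "WGQ" not in s]
        hits = scan_motifs(in_group, out_group)
        pats = [h.pattern for h in hits]
        # every reported motif must not be contained in a stronger reported one
        for i, a in enumerate(pats):
            for j, b in enumerate(pats):
                if i != j and a in b:
                    assert hits[j].p > hits[i].p

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            scan_motifs([], ["CASSF"])
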