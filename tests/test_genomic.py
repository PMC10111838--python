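import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinmat as km


def geno(dosages, pops=None, chrom=None):
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    return km.GenotypeMatrix(d, [f"i{k}" for k in range(n)],
                             [f"s{j}" for j in range(m)], chrom, pops)


class TestAlleleFrequencies:
    def test_mean_dosage_over_two(self):
        f = km.allele_frequencies(geno([[0], [2]]))
        assert f.p[0] == pytest.approx(0.5)

    def test_monomorphic(self):
        f = km.allele_frequencies(geno([[2], [2], [2]]))
        assert f.p[0] == pytest.approx(1.0)

    def test_missing_excluded(self):
        f = km.allele_frequencies(geno([[0], [1], [2], [np.nan]]))
        assert f.p[0] == pytest.approx(0.5)

    def test_all_missing_flagged(self):
        f = km.allele_frequencies(geno([[np.nan], [np.nan]]))
        assert f.all_missing[0]

    def test_by_population(self):
        g = geno([[0], [0], [2], [2]], pops=["a", "a", "b", "b"])
        fp = km.allele_frequencies(g, by_population=True)
        assert fp["a"].p[0] == pytest.approx(0.0)
        assert fp["b"].p[0] == pytest.approx(1.0)


class TestMakeG:
    def test_vanraden_hand_example(self):
        G = km.make_G(geno([[0], [2]]), "vanraden")
        np.testing.assert_allclose(G.dense(), [[2, -2], [-2, 2]], atol=1e-12)

    def test_yang_reduces_to_vanraden_single_marker(self):
        G = km.make_G(geno([[0], [2]]), "yang")
        np.testing.assert_allclose(G.dense(), [[2, -2], [-2, 2]], atol=1e-12)

    def test_yang_equals_vanraden_equal_frequencies(self):
        # every marker at p = 0.5: the per-marker scalings coincide
        rng = np.random.default_rng(0)
        d = rng.permuted(np.tile([0.0, 1.0, 1.0, 2.0], (12, 1)).T, axis=0)
        g = geno(d)  # 4 individuals x 12 markers, each column at p = 0.5
        np.testing.assert_allclose(km.make_G(g, "yang").dense(),
                                   km.make_G(g, "vanraden").dense(),
                                   atol=1e-10)

    def test_monomorphic_markers_excluded(self):
        g_with = geno([[0, 2], [2, 2], [0, 2], [2, 2]])
        g_without = geno([[0], [2], [0], [2]])
        np.testing.assert_allclose(km.make_G(g_with).dense(),
                                   km.make_G(g_without).dense(), atol=1e-12)

    def test_no_polymorphic_markers_errors(self):
        with pytest.raises(ValueError, match="polymorphic"):
            km.make_G(geno([[2], [2]]))

    def test_missing_contributes_zero(self):
        # a missing call imputed to 2p leaves that individual's centered
        # value at zero for the marker
        g = geno([[0, 0], [2, np.nan], [1, 2]])
        G = km.make_G(g)
        f = km.allele_frequencies(g)
        Xc = np.nan_to_num(g.dosages - 2 * f.p)
        denom = np.sum(2 * f.p * (1 - f.p))
        np.testing.assert_allclose(G.dense(), Xc @ Xc.T / denom, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_vanraden_allele_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, size=(8, 20)).astype(float)
        swap = rng.random(20) < 0.5
        d2 = d.copy()
        d2[:, swap] = 2.0 - d2[:, swap]
        try:
            G1 = km.make_G(geno(d), "vanraden").dense()
        except ValueError:
            return  # all markers monomorphic in this draw
        G2 = km.make_G(geno(d2), "vanraden").dense()
        np.testing.assert_allclose(G1, G2, atol=1e-10)

    def test_requires_population_labels(self):
        with pytest.raises(ValueError, match="population"):
            km.make_G(geno([[0], [2]]), "chen")

    def test_small_population_rejected(self):
        g = geno([[0], [2], [1]], pops=["a", "b", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            km.make_G(g, "chen")

    def test_chen_equals_wientjes_on_identical_populations(self):
        rng = np.random.default_rng(3)
        block = rng.integers(0, 3, size=(10, 40)).astype(float)
        d = np.vstack([block, block])  # identical genotype columns => p1j = p2j
        g = geno(d, pops=["a"] * 10 + ["b"] * 10)
        np.testing.assert_allclose(km.make_G(g, "chen").dense(),
                                   km.make_G(g, "wientjes").dense(),
                                   atol=1e-12)

    @pytest.mark.parametrize("method", ["chen", "wientjes"])
    def test_within_population_blocks_are_vanraden(self, method):
        g2 = km.simulate_two_populations(
            km.SimConfig(seed=5, n_per_pop=15, n_markers=120))
        G = km.make_G(g2, method)
        labels = np.asarray(g2.population)
        for pop in ("pop1", "pop2"):
            rows = np.flatnonzero(labels == pop)
            sub = km.GenotypeMatrix(g2.dosages[rows],
                                    [g2.individual_ids[i] for i in rows],
                                    g2.marker_ids)
            Gpop = km.make_G(sub, "vanraden").dense()
            np.testing.assert_allclose(G.dense()[np.ix_(rows, rows)], Gpop,
                                       atol=1e-10)

    def test_symmetry_and_psd(self, sim_genotypes):
        for method in ("vanraden", "yang"):
            G = km.make_G(sim_genotypes, method).dense()
            assert np.max(np.abs(G - G.T)) <= 1e-10
            assert np.linalg.eigvalsh(G).min() >= -1e-8

    def test_row_order_matches_input(self, sim_genotypes):
        G = km.make_G(sim_genotypes)
        assert G.ids == sim_genotypes.individual_ids


class TestMakeGChunked:
    @pytest.mark.parametrize("method", ["vanraden", "yang"])
    def test_chromosome_chunks_match_whole(self, sim_genotypes, method):
        whole = km.make_G(sim_genotypes, method).dense()
        chunked = km.make_G_chunked(sim_genotypes, method,
                                    chunk_by="chromosome").dense()
        assert np.max(np.abs(whole - chunked)) <= 1e-10

    @pytest.mark.parametrize("method", ["chen", "wientjes"])
    @pytest.mark.parametrize("n_blocks", [1, 4])
    def test_multipop_blocks_match_whole(self, method, n_blocks):
        g2 = km.simulate_two_populations(
            km.SimConfig(seed=7, n_per_pop=12, n_markers=100))
        whole = km.make_G(g2, method).dense()
        chunked = km.make_G_chunked(g2, method, chunk_by="marker_blocks",
                                    n_blocks=n_blocks).dense()
        assert np.max(np.abs(whole - chunked)) <= 1e-10

    def test_single_block_identical(self, sim_genotypes):
        whole = km.make_G(sim_genotypes).dense()
        one = km.make_G_chunked(sim_genotypes, chunk_by="marker_blocks",
                                n_blocks=1).dense()
        np.testing.assert_allclose(one, whole, atol=1e-12)

    def test_needs_chromosome_labels(self):
        with pytest.raises(ValueError, match="chromosome"):
            km.make_G_chunked(geno([[0, 1], [2, 1]]), chunk_by="chromosome")
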