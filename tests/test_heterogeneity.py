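import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scnahet as s
from scnahet.heterogeneity import (associate, call_breakpoints,
                                   classify_composition, cluster_clones,
                                   derive_pins, fraction_genome_subclonal,
                                   subclonal_bin_census)


def census_oracle(matrix, min_frac):
    """Brute-force per-bin state tally."""
    n_cells, n_bins = matrix.shape
    out = np.zeros(n_bins, bool)
    for j in range(n_bins):
        tally = {}
        for i in range(n_cells):
            tally[matrix[i, j]] = tally.get(matrix[i, j], 0) + 1
        qualifying = [c for c in tally.values() if c / n_cells >= min_frac]
        out[j] = len(qualifying) >= 2
    return out


class TestCensus:
    def test_identical_cells_all_clonal(self):
        m = np.full((12, 8), 2)
        assert not subclonal_bin_census(m).any()
        assert fraction_genome_subclonal(m) == 0.0

    def test_hand_census_inclusive_boundary(self):
        # 10 cells: CN 3 in 2 cells (0.2 >= 0.1), CN 2 in 8 -> sub-clonal
        m = np.full((10, 1), 2)
        m[:2, 0] = 3
        assert subclonal_bin_census(m)[0]

    def test_hand_census_minority_below_threshold(self):
        # 100 cells, CN 3 in only 5 -> 0.05 < 0.10, clonal
        m = np.full((100, 1), 2)
        m[:5, 0] = 3
        assert not subclonal_bin_census(m)[0]

    def test_toy_fraction(self):
        m = np.full((10, 5), 2)
        m[:5, 2] = 3  # exactly one sub-clonal bin of five
        assert fraction_genome_subclonal(m) == pytest.approx(20.0)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10_000), st.integers(10, 20), st.integers(1, 50))
    def test_matches_brute_force_oracle(self, seed, n_cells, n_bins):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 5, size=(n_cells, n_bins))
        np.testing.assert_array_equal(subclonal_bin_census(m),
                                      census_oracle(m, 0.10))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotone_in_min_frac(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 4, size=(15, 40))
        fracs = [fraction_genome_subclonal(m, f)
                 for f in (0.05, 0.10, 0.20, 0.34)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            subclonal_bin_census(np.empty((0, 0), int))


class TestBreakpoints:
    def test_flat_profile_none(self, small_scheme):
        assert len(call_breakpoints(np.full(30, 2), small_scheme)) == 0

    def test_left_bin_convention(self):
        bps = call_breakpoints(np.array([2, 2, 3, 3, 2]))
        np.testing.assert_array_equal(bps, [2, 4])

    def test_chromosome_boundary_not_a_breakpoint(self, small_scheme):
        n1 = small_scheme.chrom_slice("chr1").stop
        cn = np.r_[np.full(n1, 2), np.full(small_scheme.n_bins - n1, 3)]
        assert len(call_breakpoints(cn, small_scheme)) == 0


class TestPins:
    def test_clonal_above_90pct(self):
        bps = [np.array([50])] * 95 + [np.array([], int)] * 5
        pins = derive_pins(bps)
        assert pins.pins.iloc[0]["label"] == "clonal"
        assert pins.pins.iloc[0]["fraction"] == pytest.approx(0.95)

    def test_window_merge_subclonal(self):
        # breakpoints at 50/51/52 in half the cells merge to one pin
        rng = np.random.default_rng(0)
        bps = [np.array([int(rng.choice([50, 51, 52]))]) for _ in range(50)]
        bps += [np.array([], int)] * 50
        pins = derive_pins(bps, window=3)
        assert len(pins.pins) == 1
        assert pins.pins.iloc[0]["label"] == "sub-clonal"
        assert pins.pins.iloc[0]["fraction"] == pytest.approx(0.50)

    def test_rare_below_10pct(self):
        bps = [np.array([7])] * 5 + [np.array([], int)] * 95
        pins = derive_pins(bps)
        assert pins.pins.iloc[0]["label"] == "rare"

    def test_every_breakpoint_maps_to_exactly_one_pin(self):
        rng = np.random.default_rng(3)
        bps = [np.unique(rng.integers(0, 200, rng.integers(0, 6)))
               for _ in range(40)]
        pins = derive_pins(bps, window=3)
        assert (pins.pins["fraction"] <= 1.0).all()
        # each cell-breakpoint lies within the window of >= 1 pin;
        # total pin support never exceeds total breakpoint count
        anchors = pins.pins["bin"].to_numpy()
        for cell in bps:
            for b in cell:
                assert np.min(np.abs(anchors - b)) <= 2  # window width - 1

    def test_rejects_bad_window_and_single_cell(self):
        with pytest.raises(ValueError):
            derive_pins([np.array([1])] * 5, window=0)
        with pytest.raises(ValueError):
            derive_pins([np.array([1])])


class TestClustering:
    def test_two_separable_clones(self):
        a = np.full((12, 100), 2)
        b = np.full((8, 100), 2)
        b[:, 40:50] = 3  # 10 differing bins
        comp = cluster_clones(np.vstack([a, b]))
        assert len(comp.frequencies) == 2
        labels = comp.assignments
        assert len(set(labels[:12])) == 1 and len(set(labels[12:])) == 1
        assert labels[0] != labels[12]
        assert comp.composition_class == "dominant"

    def test_single_clone(self):
        comp = cluster_clones(np.full((20, 50), 2))
        assert comp.composition_class == "homogeneous"

    def test_three_noisy_clones_recovered(self, genome_scheme):
        clones = [
            s.CloneSpec("A", 0.5, events=[
                s.CNAEvent("chr8", 46_000_000, 146_000_000, delta=1)]),
            s.CloneSpec("B", 0.3, parent="A", events=[
                s.CNAEvent("chr13", 1, 115_000_000, delta=-1)]),
            s.CloneSpec("C", 0.2, parent="A", events=[
                s.CNAEvent("chr1", 125_000_000, 249_000_000, delta=1)]),
        ]
        cfg = s.SimConfig(clones=clones, n_cells=60, reads_per_cell=400_000,
                          n_bins=800)
        sim = s.simulate_sample(cfg, seed=21)
        called = np.vstack([s.call_cell(sim.counts[i], sim.scheme, seed=0).cn
                            for i in range(60)])
        comp = cluster_clones(called)
        from sklearn.metrics import adjusted_rand_score
        ari = adjusted_rand_score(sim.truth.labels, comp.assignments)
        assert ari >= 0.9


class TestComposition:
    @pytest.mark.parametrize("freqs,expected", [
        ([1.0], "homogeneous"),
        ([0.97, 0.03], "homogeneous"),       # within the 5% tolerance
        ([0.6, 0.3, 0.1], "dominant"),
        ([0.4, 0.35, 0.25], "no-dominant"),
        ([0.5, 0.5], "no-dominant"),         # > 0.5 is strict
    ])
    def test_rules(self, freqs, expected):
        assert classify_composition(freqs) == expected

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            classify_composition([])


class TestAssociate:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(0)
        v = np.r_[rng.normal(0, 1, 30), rng.normal(0, 1, 30)]
        g = np.array(["a"] * 30 + ["b"] * 30)
        res = associate(v, g)
        assert res.method == "wilcoxon-rank-sum"
        assert res.p_value > 0.05

    def test_perfect_separation_minimal_rank_sum(self):
        v = np.arange(1, 11, dtype=float)
        g = np.array(["low"] * 5 + ["high"] * 5)
        res = associate(v, g)
        # perfect separation: minimal U statistic, and the exact two-sided
        # enumeration gives 2 / C(10,5) extreme orderings
        assert min(res.statistic, 25 - res.statistic) == 0
        assert res.p_value == pytest.approx(2 / 252, rel=1e-6)

    def test_monotone_gives_spearman_rho_one(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = x ** 3
        res = associate(x, y)
        assert res.method == "spearman"
        assert res.statistic == pytest.approx(1.0)

    def test_tiny_group_flagged(self):
        res = associate(np.array([1.0, 2, 3]), np.array(["a", "a", "b"]))
        assert np.isnan(res.p_value) and res.note
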