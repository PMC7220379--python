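import numpy as np
import pytest

import scnahet as s
from scnahet.genome import make_bin_scheme
from tests.conftest import two_clone_config


class TestReproducibility:
    def test_identical_config_seed_bit_identical(self):
        cfg = two_clone_config(n_cells=20, reads_per_cell=50_000, n_bins=300,
                               n_t_cells=2, n_b_cells=1, n_pseudo_diploid=1)
        a = s.simulate_sample(cfg, seed=11)
        b = s.simulate_sample(cfg, seed=11)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.truth.cn, b.truth.cn)
        assert list(a.truth.labels) == list(b.truth.labels)

    def test_different_seed_differs(self):
        cfg = two_clone_config(n_cells=20, reads_per_cell=50_000, n_bins=300,
                               n_t_cells=2, n_b_cells=1, n_pseudo_diploid=1)
        a = s.simulate_sample(cfg, seed=11)
        b = s.simulate_sample(cfg, seed=12)
        assert np.any(a.counts != b.counts)


class TestConservationAndTruth:
    def test_counts_sum_to_reads_per_cell(self, two_clone_sim):
        assert np.all(two_clone_sim.counts.sum(axis=1) == 500_000)

    def test_truth_breakpoints_match_cn_changes(self, two_clone_sim):
        scheme = two_clone_sim.scheme
        same = scheme.same_chrom_as_prev()
        for i in range(two_clone_sim.counts.shape[0]):
            cn = two_clone_sim.truth.cn[i]
            change = np.zeros(len(cn), bool)
            change[1:] = cn[1:] != cn[:-1]
            np.testing.assert_array_equal(
                two_clone_sim.truth.breakpoints[i],
                np.flatnonzero(change & same))

    def test_labels_partition_cells(self, two_clone_sim):
        labels = two_clone_sim.truth.labels
        assert len(labels) == two_clone_sim.counts.shape[0]
        counts = {lab: int(np.sum(labels == lab)) for lab in set(labels)}
        assert counts["T-cell"] + counts["X-loss-T"] == 6
        assert counts["B-cell"] == 2
        assert counts["pseudo-diploid"] == 2

    def test_null_configuration_all_flat(self):
        cfg = s.SimConfig(clones=[s.CloneSpec("A", 1.0)], n_cells=10,
                          reads_per_cell=20_000, n_bins=200)
        sim = s.simulate_sample(cfg, seed=1)
        assert np.all(sim.truth.cn == 2)
        assert all(str(lab).startswith("cancer") for lab in sim.truth.labels)

    def test_subclonal_event_registered_at_its_fraction(self):
        clones = [s.CloneSpec("A", 0.6),
                  s.CloneSpec("B", 0.4, events=[
                      s.CNAEvent("chr8", 46_000_000, 146_000_000, delta=1,
                                 name="8q+")])]
        cfg = s.SimConfig(clones=clones, n_cells=100, reads_per_cell=20_000,
                          n_bins=300)
        sim = s.simulate_sample(cfg, seed=7)
        (ev,) = sim.truth.events
        assert ev["name"] == "8q+"
        assert ev["cell_fraction"] == pytest.approx(0.40)
        assert not ev["clonal"]

    def test_inherited_event_is_clonal(self):
        clones = [s.CloneSpec("A", 0.6, events=[
                      s.CNAEvent("chr1", 125_000_000, 249_000_000, delta=1,
                                 name="1q+")]),
                  s.CloneSpec("B", 0.4, parent="A")]
        cfg = s.SimConfig(clones=clones, n_cells=50, reads_per_cell=20_000,
                          n_bins=300)
        sim = s.simulate_sample(cfg, seed=7)
        (ev,) = sim.truth.events
        assert ev["clonal"] and ev["cell_fraction"] == pytest.approx(1.0)


class TestErrors:
    def test_rejects_overcommitted_fractions(self):
        cfg = s.SimConfig(clones=[s.CloneSpec("A", 0.7), s.CloneSpec("B", 0.6)])
        with pytest.raises(ValueError, match="exceed 1"):
            s.simulate_sample(cfg, seed=1)

    def test_rejects_zero_reads(self):
        with pytest.raises(ValueError, match="reads_per_cell"):
            s.simulate_sample(s.SimConfig(reads_per_cell=0), seed=1)

    def test_rejects_event_below_zero_cn(self):
        cfg = s.SimConfig(clones=[s.CloneSpec("A", 1.0, events=[
            s.CNAEvent("chr1", 1, 10_000_000, delta=-3)])], n_cells=2,
            reads_per_cell=10_000, n_bins=100)
        with pytest.raises(ValueError, match="below 0"):
            s.simulate_sample(cfg, seed=1)


class TestImmuneTruth:
    def test_t_cell_deletions_focal_homozygous_in_window(self):
        cfg = s.SimConfig(n_cells=95, n_t_cells=95, reads_per_cell=10_000,
                          n_bins=2000)
        sim = s.simulate_sample(cfg, seed=5)
        for i, dels in sim.truth.deletions.items():
            for locus, lo, hi in dels:
                assert 1 <= hi - lo <= 3
                assert np.all(sim.truth.cn[i, lo:hi] == 0)

    def test_breakpoints_mostly_distinct_across_t_cells(self):
        """Independent recombination events over a ~14-bin span rarely
        collide, so most pairwise breakpoint pairs are distinct."""
        cfg = s.SimConfig(n_cells=95, n_t_cells=95, reads_per_cell=10_000,
                          n_bins=2000)
        sim = s.simulate_sample(cfg, seed=5)
        tcra = [tuple(d[1:]) for dels in sim.truth.deletions.values()
                for d in dels if d[0] == "TCRA"]
        assert len(tcra) == 95
        n_pairs = n_distinct = 0
        for i in range(len(tcra)):
            for j in range(i + 1, len(tcra)):
                n_pairs += 1
                n_distinct += tcra[i] != tcra[j]
        assert n_distinct / n_pairs > 0.9


@pytest.fixture(scope="module")
def clones():
    return [s.CloneSpec("A", 0.5),
            s.CloneSpec("B", 0.5, events=[
                s.CNAEvent("chr2", 1, 60_000_000, delta=1, name="2p+")])]


class TestBulkPair:

    def test_identical_mixtures_no_differentials(self, clones):
        scheme = make_bin_scheme(300)
        a, b, diffs = s.simulate_bulk_pair({"A": 1.0}, {"A": 1.0}, clones,
                                           scheme)
        assert diffs == [] and np.array_equal(a, b)

    def test_private_clone_interval_is_differential(self, clones):
        scheme = make_bin_scheme(300)
        a, b, diffs = s.simulate_bulk_pair({"A": 1.0}, {"B": 1.0}, clones,
                                           scheme)
        lo, hi = scheme.interval_to_bins("chr2", 1, 60_000_000)
        assert len(diffs) == 1
        assert (diffs[0]["start"], diffs[0]["end"]) == (lo, hi)

    def test_mixture_equals_weighted_mean_oracle(self, clones):
        scheme = make_bin_scheme(300)
        mix = {"A": 0.3, "B": 0.7}
        a, _, _ = s.simulate_bulk_pair(mix, {"A": 1.0}, clones, scheme)
        # brute-force per-bin weighted mean over clone CN vectors
        from scnahet.simulate import _clone_cn
        reg = {c.clone_id: c for c in clones}
        expect = np.rint(0.3 * _clone_cn(reg["A"], reg, scheme)
                         + 0.7 * _clone_cn(reg["B"], reg, scheme)).astype(int)
        np.testing.assert_array_equal(a, expect)

    def test_rejects_empty_mixture(self, clones):
        with pytest.raises(ValueError, match="empty mixture"):
            s.simulate_bulk_pair({}, {"A": 1.0}, clones, make_bin_scheme(100))
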