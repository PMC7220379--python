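import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scnahet as s
from scnahet.immune import (LocusRegistry, clonality_permutation_test,
                            detect_vdj_deletions, detect_x_loss,
                            detection_sensitivity, is_flat_diploid,
                            tcr_breakpoint_distance)


@pytest.fixture(scope="module")
def scheme():
    return s.make_bin_scheme(2000)


@pytest.fixture(scope="module")
def registry():
    return LocusRegistry()


def _flat(scheme):
    return np.full(scheme.n_bins, 2, dtype=int)


class TestFlatDiploid:
    def test_all_two_is_flat(self, scheme):
        assert is_flat_diploid(_flat(scheme), scheme)

    def test_30pct_aberrant_not_flat(self, scheme):
        cn = _flat(scheme)
        n = int(0.3 * scheme.n_bins)
        cn[:n] = 3
        assert not is_flat_diploid(cn, scheme)

    def test_small_deletion_within_tolerance(self, scheme, registry):
        cn = _flat(scheme)
        lo, hi = registry.resolve(scheme)["TCRA"]
        cn[lo:lo + 2] = 0  # 2 bins of 2000 < 2%
        assert is_flat_diploid(cn, scheme)

    def test_x_loss_does_not_affect_autosomal_census(self, scheme):
        cn = _flat(scheme)
        xs = scheme.chrom_slice("chrX")
        cn[xs] = 1
        assert is_flat_diploid(cn, scheme)


class TestVdjDetection:
    def test_tcra_deletion_called_t(self, scheme, registry):
        cn = _flat(scheme)
        lo, _ = registry.resolve(scheme)["TCRA"]
        cn[lo:lo + 2] = 0
        call = detect_vdj_deletions(cn, scheme, registry)
        assert call.cell_class == "T"
        assert call.deletions == [("TCRA", lo, lo + 2)]

    def test_igh_igl_without_tcr_is_b(self, scheme, registry):
        cn = _flat(scheme)
        res = registry.resolve(scheme)
        for locus in ("IGH", "IGL"):
            lo, _ = res[locus]
            cn[lo:lo + 1] = 0
        call = detect_vdj_deletions(cn, scheme, registry)
        assert call.cell_class == "B"
        assert {d[0] for d in call.deletions} == {"IGH", "IGL"}

    def test_flat_everywhere_is_stromal(self, scheme, registry):
        call = detect_vdj_deletions(_flat(scheme), scheme, registry)
        assert call.cell_class == "flat-stromal"
        assert call.deletions == []

    def test_hemizygous_dip_not_evidence(self, scheme, registry):
        cn = _flat(scheme)
        lo, _ = registry.resolve(scheme)["TCRA"]
        cn[lo:lo + 2] = 1
        assert detect_vdj_deletions(cn, scheme, registry).cell_class \
            == "flat-stromal"

    def test_x_loss_t_cell(self, scheme, registry):
        cn = _flat(scheme)
        lo, _ = registry.resolve(scheme)["TCRA"]
        cn[lo:lo + 1] = 0
        cn[scheme.chrom_slice("chrX")] = 1
        assert detect_vdj_deletions(cn, scheme, registry).cell_class \
            == "X-loss-T"


class TestXLoss:
    def test_whole_x_at_one(self, scheme):
        cn = _flat(scheme)
        cn[scheme.chrom_slice("chrX")] = 1
        assert detect_x_loss(cn, scheme, expected_x_cn=2)

    def test_normal_female_x(self, scheme):
        assert not detect_x_loss(_flat(scheme), scheme, expected_x_cn=2)

    def test_partial_loss_rejected_by_90pct_rule(self, scheme):
        cn = _flat(scheme)
        xs = scheme.chrom_slice("chrX")
        half = (xs.start + xs.stop) // 2
        cn[xs.start:half] = 1
        assert not detect_x_loss(cn, scheme, expected_x_cn=2)


class TestBreakpointDistance:
    def test_identical_zero(self):
        assert tcr_breakpoint_distance((10, 12), (10, 12)) == 0

    def test_formula(self):
        assert tcr_breakpoint_distance((10, 15), (12, 18)) == 5

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(st.integers(0, 50), st.integers(0, 50)),
           st.tuples(st.integers(0, 50), st.integers(0, 50)),
           st.tuples(st.integers(0, 50), st.integers(0, 50)))
    def test_metric_properties(self, a, b, c):
        d = tcr_breakpoint_distance
        assert d(a, b) >= 0
        assert d(a, b) == d(b, a)
        assert (d(a, b) == 0) == (a == b)
        assert d(a, c) <= d(a, b) + d(b, c)

    def test_missing_deletion_rejected(self):
        with pytest.raises(ValueError):
            tcr_breakpoint_distance(None, (1, 2))


class TestClonalityTest:
    def test_all_unique_pool_p_below_floor(self):
        pool = [(i, i + 2) for i in range(20)]
        res = clonality_permutation_test(pool[:5], pool, n_perm=10_000, seed=1)
        assert res.hits == 0
        assert res.p_value == pytest.approx(1 / 10_001)
        assert res.p_report.startswith("<")

    def test_fully_clonal_pool_p_one(self):
        pool = [(4, 6)] * 15
        res = clonality_permutation_test(pool[:4], pool, n_perm=5_000, seed=1)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("k,N,g", [(5, 12, 3), (8, 20, 4), (10, 15, 5)])
    def test_matches_hypergeometric_closed_form(self, k, N, g):
        """k identical cells among N otherwise-unique: P(uniform draw of g)
        = C(k,g)/C(N,g), within Monte-Carlo error."""
        pool = [(0, 1)] * k + [(i + 10, i + 12) for i in range(N - k)]
        n_perm = 40_000
        res = clonality_permutation_test(pool[:g], pool, n_perm=n_perm, seed=7)
        p_true = math.comb(k, g) / math.comb(N, g)
        sigma = math.sqrt(p_true * (1 - p_true) / n_perm)
        assert abs(res.hits / n_perm - p_true) < 3 * sigma + 1e-9

    def test_rejects_degenerate_group(self):
        with pytest.raises(ValueError):
            clonality_permutation_test([(1, 2)], [(1, 2)] * 5)


class TestSensitivity:
    def test_all_correct(self):
        assert detection_sensitivity(
            [s.ImmuneCall("c", "T")] * 4, "T") == 1.0

    def test_half_correct(self):
        calls = [s.ImmuneCall(str(i), "T") for i in range(48)] + \
                [s.ImmuneCall(str(i), "flat-stromal") for i in range(48)]
        assert detection_sensitivity(calls, "T") == pytest.approx(0.5)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            detection_sensitivity([], "T")

    def test_simulated_purified_t_cells_high_sensitivity(self):
        """Purified T-cells with 2-bin deletions at 2M reads are nearly
        always recovered (detection limited only by counting noise)."""
        cfg = s.SimConfig(n_cells=24, n_t_cells=24, reads_per_cell=2_000_000,
                          n_bins=2000, deletion_width=(2, 2))
        sim = s.simulate_sample(cfg, seed=13)
        registry = LocusRegistry()
        calls = []
        for i in range(24):
            prof = s.call_cell(sim.counts[i], sim.scheme, seed=0)
            calls.append(detect_vdj_deletions(prof.cn, sim.scheme, registry))
        sens = detection_sensitivity(
            [c if c.cell_class != "X-loss-T" else
             s.ImmuneCall(c.cell_id, "T", c.deletions) for c in calls], "T")
        assert sens >= 0.9


def _small():
    return s.make_bin_scheme(30, {"chr1": 20_000_000, "chr2": 10_000_000})


class TestPseudoDiploid:
    def test_flat_cell_is_not_pseudo_diploid(self, scheme):
        from scnahet.immune import classify_pseudo_diploid
        assert classify_pseudo_diploid(_flat(scheme), scheme,
                                       np.array([100])) == "flat"

    def test_private_gain_unrelated_to_tumor(self, scheme):
        from scnahet.immune import classify_pseudo_diploid
        cn = _flat(scheme)
        q1 = scheme.interval_to_bins("chr1", 125_000_000, 249_000_000)
        cn[q1[0]:q1[1]] = 3
        tumor_pins = np.array([1500, 1600])  # far from the 1q boundary
        assert classify_pseudo_diploid(cn, scheme, tumor_pins) \
            == "pseudo-diploid"

    def test_cell_matching_clonal_pins_is_cancer(self, scheme):
        from scnahet.immune import classify_pseudo_diploid
        cn = _flat(scheme)
        q1 = scheme.interval_to_bins("chr1", 125_000_000, 249_000_000)
        cn[q1[0]:q1[1]] = 3
        assert classify_pseudo_diploid(cn, scheme, np.array([q1[0]])) \
            == "cancer"

    def test_no_signature_unassigned(self, scheme):
        from scnahet.immune import classify_pseudo_diploid
        cn = _flat(scheme)
        cn[:100] = 3
        assert classify_pseudo_diploid(cn, scheme, None) \
            == "aberrant-unassigned"
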