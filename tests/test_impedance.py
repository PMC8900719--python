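import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import meamask as mm
from meamask.errors import (AlignmentError, CapacityError,
                            InvalidParameterError)
from meamask.geometry import COVERED
from meamask.impedance import YieldCounts, peak_to_peak_rows


class TestPlanPatches:
    def test_default_plan_tiles_acquired_region(self, grid, patches):
        assert len(patches) == 25
        assert all(len(p) == 1008 for p in patches)
        # brute-force set check: disjoint cover of rows 0-119 x cols 0-209
        seen = np.zeros(grid.n_electrodes, dtype=int)
        for p in patches:
            seen[p.electrodes] += 1
        rows, cols = np.divmod(np.arange(grid.n_electrodes), grid.n_cols)
        np.testing.assert_array_equal(seen, (cols < 210).astype(int))

    def test_patches_are_contiguous_rectangles(self, grid, patches):
        for p in patches:
            rows, cols = grid.index_to_rowcol(p.electrodes)
            nr = rows.max() - rows.min() + 1
            nc = cols.max() - cols.min() + 1
            assert nr * nc == len(p)

    def test_capacity_enforced(self):
        with pytest.raises(CapacityError):
            mm.RoutingPattern(np.arange(1025))

    def test_x_max_beyond_grid_rejected(self, grid):
        with pytest.raises(InvalidParameterError):
            mm.plan_patches(grid, x_max=230)


class TestPeakToPeak:
    def test_constant_trace_is_zero(self):
        assert mm.peak_to_peak(np.full(1000, 3.3)) == 0.0

    def test_pure_sine_gives_twice_amplitude(self):
        t = np.arange(2000) / 20000.0
        trace = 8.0 * np.sin(2 * np.pi * 1000.0 * t)
        assert mm.peak_to_peak(trace) == pytest.approx(16.0, rel=0.01)

    def test_noisy_sine_within_five_percent(self):
        rng = np.random.default_rng(0)
        t = np.arange(100000) / 20000.0
        trace = (8.0 * np.sin(2 * np.pi * 1000.0 * t)
                 + rng.normal(0, 0.3, t.size))
        assert mm.peak_to_peak(trace) == pytest.approx(16.0, rel=0.05)

    def test_too_short_trace_rejected(self):
        with pytest.raises(InvalidParameterError):
            mm.peak_to_peak(np.array([1.0]))

    def test_percentile_mode_resists_outliers(self):
        trace = np.zeros(10000)
        trace[::500] = 50.0  # 0.2% outliers, outside the 0.5% clip
        assert mm.peak_to_peak(trace) < mm.peak_to_peak(trace, method="raw")


@pytest.fixture(scope="module")
def noiseless_map(rasterized, patches, grid):
    cov, _ = rasterized
    params = mm.ImpedanceSimParams(duration_s=0.05, noise_sd=0.0)
    recs = mm.simulate_impedance_patches(cov, patches, params)
    return mm.assemble_map(recs, patches, grid), recs


class TestAssembleAndClassify:
    def test_noiseless_map_is_exact_per_label(self, noiseless_map,
                                              rasterized):
        imap, _ = noiseless_map
        cov, _ = rasterized
        amps = imap.amplitudes
        acq = ~imap.missing
        np.testing.assert_allclose(amps[acq & cov.uncovered], 16.0 * 0.95,
                                   atol=1e-5)
        np.testing.assert_allclose(amps[acq & cov.covered], 16.0 * 0.03,
                                   atol=1e-5)

    def test_patch_order_is_irrelevant(self, noiseless_map, patches, grid):
        imap, recs = noiseless_map
        perm = np.random.default_rng(1).permutation(len(patches))
        imap2 = mm.assemble_map([recs[i] for i in perm],
                                [patches[i] for i in perm], grid)
        np.testing.assert_array_equal(imap.amplitudes, imap2.amplitudes)

    def test_shape_mismatch_rejected(self, patches, grid):
        good = [np.zeros((len(p), 100)) for p in patches]
        good[3] = np.zeros((5, 100))
        with pytest.raises(AlignmentError):
            mm.assemble_map(good, patches, grid)

    def test_noiseless_classification_recovers_truth(self, noiseless_map,
                                                     rasterized):
        imap, _ = noiseless_map
        cov, _ = rasterized
        measured = mm.classify_coverage(imap, threshold=8.0)
        acq = ~measured.missing
        np.testing.assert_array_equal(measured.labels[acq],
                                      cov.labels[acq])

    def test_zero_threshold_covers_nothing(self, noiseless_map):
        imap, _ = noiseless_map
        measured = mm.classify_coverage(imap, threshold=0.0)
        assert not measured.covered.any()

    def test_otsu_agrees_with_fixed_threshold_on_bimodal_map(
            self, rasterized, patches, grid):
        cov, _ = rasterized
        params = mm.ImpedanceSimParams(duration_s=0.05, seed=3)
        imap = mm.simulate_impedance_map(cov, patches, params, grid)
        fixed = mm.classify_coverage(imap, threshold=8.0)
        otsu = mm.classify_coverage(imap, threshold="otsu")
        np.testing.assert_array_equal(fixed.labels, otsu.labels)

    def test_amplitude_histogram_is_cleanly_bimodal(self, rasterized,
                                                    patches, grid):
        # the underlying sine amplitudes differ ~30-fold; after noise the
        # estimated clusters must still be far apart and non-overlapping
        cov, _ = rasterized
        params = mm.ImpedanceSimParams(duration_s=0.05, seed=4)
        imap = mm.simulate_impedance_map(cov, patches, params, grid)
        acq = ~imap.missing
        covered = imap.amplitudes[acq & cov.covered]
        uncovered = imap.amplitudes[acq & cov.uncovered]
        assert uncovered.mean() > 5 * covered.mean()
        assert uncovered.min() > 5 * covered.max()

    def test_all_missing_map_rejected(self, grid):
        empty = mm.ImpedanceMap(np.full((grid.n_rows, grid.n_cols), np.nan))
        with pytest.raises(InvalidParameterError):
            mm.classify_coverage(empty)


class TestAgreement:
    def test_identity_is_100_percent(self, rasterized):
        cov, _ = rasterized
        measured = mm.CoverageMap(cov.labels.copy(), "measured")
        assert mm.compare_expected_measured(cov, measured).percent == 100.0

    def test_all_covered_is_zero_percent(self, rasterized):
        cov, _ = rasterized
        measured = mm.CoverageMap(np.full_like(cov.labels, COVERED),
                                  "measured")
        assert mm.compare_expected_measured(cov, measured).percent == 0.0

    def test_relabeling_outside_expected_uncovered_is_irrelevant(
            self, rasterized):
        cov, _ = rasterized
        measured = mm.CoverageMap(cov.labels.copy(), "measured")
        base = mm.compare_expected_measured(cov, measured).percent
        flipped = measured.copy()
        outside = cov.covered
        flipped.labels[outside] = mm.UNCOVERED  # expose mask body
        assert mm.compare_expected_measured(cov, flipped).percent == base

    def test_no_expected_uncovered_rejected(self, rasterized):
        cov, _ = rasterized
        expected = mm.CoverageMap(np.full_like(cov.labels, COVERED),
                                  "expected")
        with pytest.raises(InvalidParameterError):
            mm.compare_expected_measured(expected, cov)

    def test_per_network_breakdown(self, grid):
        da = mm.generate_network_design(center=(700.0, 1050.0),
                                        network_id="a")
        db = mm.generate_network_design(center=(2800.0, 1050.0),
                                        network_id="b")
        cov, _ = mm.rasterize_design(mm.MicrostructureLayout([da, db]), grid)
        ca, _ = mm.rasterize_design(mm.MicrostructureLayout([da]), grid)
        cb, _ = mm.rasterize_design(mm.MicrostructureLayout([db]), grid)
        res = mm.compare_expected_measured(
            cov, mm.CoverageMap(cov.labels.copy(), "measured"),
            network_masks=[ca.uncovered, cb.uncovered])
        assert res.per_network_percent == [100.0, 100.0]
        assert res.network_mean == 100.0
        assert res.network_sd == 0.0


class TestOpenness:
    def test_unclogged_network_is_open(self, rasterized):
        cov, groups = rasterized
        measured = mm.CoverageMap(cov.labels.copy(), "measured")
        a = mm.assess_openness(measured, groups)
        assert a.covered_fully_by_sensor and a.open is True

    def test_fully_clogged_channel_closes_network(self, grid, rasterized):
        cov, groups = rasterized
        measured = mm.CoverageMap(cov.labels.copy(), "measured")
        # clog channel 2: its footprint plus a 1-electrode margin covered
        chan = np.asarray(groups.channel_electrodes[2], dtype=np.int64)
        rows, cols = grid.index_to_rowcol(chan)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                measured.labels[rows + dr, cols + dc] = COVERED
        a = mm.assess_openness(measured, groups)
        assert a.open is False

    def test_network_off_acquired_region_not_fully_covered(self, grid):
        # a network straddling the x = 210-column acquisition boundary
        design = mm.generate_network_design(center=(3500.0, 1050.0),
                                            network_id="edge")
        cov, groups = mm.rasterize_design(
            mm.MicrostructureLayout([design]), grid)
        labels = cov.labels.copy()
        labels[:, 210:] = mm.MISSING
        a = mm.assess_openness(mm.CoverageMap(labels, "measured"), groups[0])
        assert a.covered_fully_by_sensor is False
        assert a.open is None

    def test_activity_update_requires_open_for_full_connectivity(
            self, rasterized):
        cov, groups = rasterized
        a = mm.assess_openness(mm.CoverageMap(cov.labels.copy(), "measured"),
                               groups)
        assert a.with_activity(4).fully_connected is True
        assert a.with_activity(3).fully_connected is False


class TestRoutingSelection:
    def test_small_region_fully_selected(self):
        pattern, counts = mm.select_routing(np.arange(760))
        assert counts == {"selected": 760, "routed": 760}
        assert len(pattern) == 760

    def test_large_region_capped_at_capacity(self):
        pattern, counts = mm.select_routing(np.arange(2000))
        assert counts["routed"] == 1024
        assert len(pattern) == 1024

    def test_decimation_is_deterministic(self):
        region = np.random.default_rng(2).choice(26400, size=1500,
                                                 replace=False)
        a, _ = mm.select_routing(region)
        b, _ = mm.select_routing(region)
        np.testing.assert_array_equal(a.electrodes, b.electrodes)

    def test_empty_region_rejected(self):
        with pytest.raises(InvalidParameterError):
            mm.select_routing(np.array([], dtype=int))


class TestYieldSummary:
    def test_zero_open_networks(self):
        counts = YieldCounts(47, 0, 0, 0, 14, 0, 0, 760, 685)
        assert mm.summarize_yield(counts).percentages[
            "open_of_covered_pct"] == 0.0

    def test_zero_denominator_omitted_with_warning(self):
        counts = YieldCounts(10, 2, 1, 0, 3, 1, 0, 0, 0)
        with pytest.warns(UserWarning):
            summary = mm.summarize_yield(counts)
        assert "routed_of_selected_pct" not in summary.percentages
        assert summary.percentages["open_of_covered_pct"] == 20.0

    @given(st.integers(min_value=1, max_value=50))
    def test_percentages_scale_invariant(self, k):
        base = YieldCounts(47, 11, 9, 5, 14, 6, 2, 760, 685)
        scaled = YieldCounts(*(k * v for v in (47, 11, 9, 5, 14, 6, 2,
                                               760, 685)))
        assert (mm.summarize_yield(base).percentages
                == mm.summarize_yield(scaled).percentages)

    def test_counts_from_assessments(self):
        open_net = mm.NetworkAssessment("a", True, True).with_activity(4)
        closed = mm.NetworkAssessment("b", True, False).with_activity(1)
        off = mm.NetworkAssessment("c", False, None)
        counts = mm.counts_from_assessments(
            {"mea0": [open_net, closed], "mea1": [off]},
            electrodes_selected=100, electrodes_routed=90)
        assert counts.networks_covered == 2
        assert counts.networks_open == 1
        assert counts.networks_active == 2
        assert counts.networks_fully_connected == 1
        assert counts.meas_total == 2
        assert counts.meas_active == 1
        assert counts.meas_fully_connected == 1


def test_vectorized_peak_to_peak_matches_scalar():
    rng = np.random.default_rng(5)
    traces = rng.normal(size=(7, 4000))
    np.testing.assert_allclose(
        peak_to_peak_rows(traces),
        [mm.peak_to_peak(t) for t in traces], rtol=1e-12)
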