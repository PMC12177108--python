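"""Phase estimation, phase sorting, RVent/VDP and FVL cross-correlation."""

import numpy as np
import pytest

from prefulvent import (
    DynamicSeries,
    LungMask,
    PhantomParams,
    build_reference_fvl,
    compute_rvent,
    estimate_phase,
    fvl_cc_map,
    sort_to_cycle,
    synthesize_series,
    vdp_rvent,
)
from prefulvent.core import PhaseAssignment, PhaseResolvedCycle
from prefulvent.exceptions import (
    InsufficientSamplingError,
    InvalidParameterError,
    PhaseEstimationError,
)


def circular_rms(a: np.ndarray, b: np.ndarray) -> float:
    err = np.angle(np.exp(1j * (a - b)))
    return float(np.sqrt(np.mean(err**2)))


def _uniform_cycle(values: np.ndarray, mask_shape=(16, 16), n_bins=12) -> tuple:
    """Cycle whose in-lung signal is spatially uniform per bin; values gives
    the per-bin level. Key-state indices follow the min/max convention."""
    mask = np.ones(mask_shape, bool)
    sig = np.ones(mask_shape + (n_bins,)) * np.asarray(values)[None, None, :]
    idx_insp = int(np.argmin(values))
    idx_exp = int(np.argmax(values))
    centers = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    fwd = (centers[idx_insp] - centers[idx_exp]) % (2 * np.pi)
    mid_phase = (centers[idx_exp] + fwd / 2) % (2 * np.pi)
    d = np.abs(centers - mid_phase)
    idx_mid = int(np.argmin(np.minimum(d, 2 * np.pi - d)))
    cycle = PhaseResolvedCycle(
        sig, centers, np.ones(n_bins, int), idx_insp, idx_exp, idx_mid
    )
    return cycle, LungMask(mask)


class TestEstimatePhase:
    def test_frequency_recovered_within_one_percent(self, analyzed_small, small_params):
        result, _ = analyzed_small
        f_true = 1.0 / small_params.respiratory_period
        assert result.phases.respiratory_frequency == pytest.approx(f_true, rel=0.01)

    def test_phase_trace_recovered(self, analyzed_small):
        result, truth = analyzed_small
        assert circular_rms(result.phases.phase_per_frame, truth.phase_trace) <= 0.1

    def test_tracks_period_jitter(self):
        p = PhantomParams(grid_size=64, period_jitter_cv=0.08, seed=13)
        series, truth = synthesize_series(p)
        mask = LungMask(truth.lung_mask)
        from prefulvent.preprocess import lowpass_filter

        phases = estimate_phase(lowpass_filter(series), mask)
        assert circular_rms(phases.phase_per_frame, truth.phase_trace) <= 0.3

    def test_constant_signal_is_error(self):
        t = np.arange(100) * 0.135
        series = DynamicSeries(np.full((16, 16, 100), 50.0), t)
        with pytest.raises(PhaseEstimationError):
            estimate_phase(series, LungMask(np.ones((16, 16), bool)))

    def test_noise_only_signal_is_error(self, rng):
        t = np.arange(100) * 0.135
        series = DynamicSeries(50 + rng.standard_normal((16, 16, 100)), t)
        with pytest.raises(PhaseEstimationError):
            estimate_phase(series, LungMask(np.ones((16, 16), bool)))


class TestSortToCycle:
    def test_uniform_coverage_no_merging(self, analyzed_small):
        result, _ = analyzed_small
        cycle = result.cycle
        assert cycle.n_bins == 15
        assert np.all(cycle.bin_counts >= 1)
        assert cycle.n_merged == 0

    def test_polarity_and_monotone_inspiratory_limb(self, analyzed_small):
        result, truth = analyzed_small
        cycle = result.cycle
        lung = truth.lung_mask
        means = cycle.signal[lung].mean(axis=0)
        assert means[cycle.idx_insp] <= means[cycle.idx_exp]
        # walk the inspiratory limb (exp -> insp, increasing phase): the mean
        # lung signal of the programmed cosine decreases monotonically
        n = cycle.n_bins
        limb = [(cycle.idx_exp + k) % n for k in range((cycle.idx_insp - cycle.idx_exp) % n + 1)]
        assert np.all(np.diff(means[limb]) < 0)

    def test_degenerate_phases_error(self, small_phantom):
        series, truth = small_phantom
        phases = PhaseAssignment(np.zeros(series.n_frames), 0.25, 1.0)
        with pytest.raises(InsufficientSamplingError):
            sort_to_cycle(series, phases, LungMask(truth.lung_mask))

    def test_too_few_bins_rejected(self, analyzed_small, small_phantom):
        result, truth = analyzed_small
        series, _ = small_phantom
        with pytest.raises(InvalidParameterError):
            sort_to_cycle(series, result.phases, LungMask(truth.lung_mask), n_bins=5)


class TestRVent:
    def test_printed_formula_arithmetic(self):
        # S_Mid=90, S_Insp=80, S_Exp=100 -> 90/80 - 90/100 = 0.225
        n_bins = 12
        sig = np.full((16, 16, n_bins), 100.0)
        sig[:, :, 3] = 80.0
        sig[:, :, 9] = 90.0
        centers = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
        cycle = PhaseResolvedCycle(
            sig, centers, np.ones(n_bins, int), idx_insp=3, idx_exp=0, idx_mid=9
        )
        mask = LungMask(np.ones((16, 16), bool))
        rvent, n_bad = compute_rvent(cycle, mask)
        assert n_bad == 0
        assert np.allclose(rvent[mask.lung], 0.225, rtol=1e-12)

    def test_flat_cycle_gives_zero(self):
        cycle, mask = _uniform_cycle(np.full(12, 100.0))
        rvent, _ = compute_rvent(cycle, mask)
        assert np.allclose(rvent[mask.lung], 0.0)

    def test_uniform_phantom_spatially_constant(self):
        p = PhantomParams(grid_size=64, amplitude_cv=0.0, perfusion_amplitude=0.0, seed=2)
        series, truth = synthesize_series(p)
        mask = LungMask(truth.lung_mask)
        phases = estimate_phase(series, mask)
        cycle = sort_to_cycle(series, phases, mask)
        rvent, _ = compute_rvent(cycle, mask)
        vals = rvent[mask.lung]
        assert np.ptp(vals) / np.mean(vals) < 0.01


def _brute_force_vdp(values: np.ndarray, factor=0.4, pct=90.0) -> tuple[float, float]:
    """Sort-and-count VDP oracle with linear-interpolation percentiles."""
    v = np.sort(values)
    rank = (v.size - 1) * pct / 100.0
    lo, hi = int(np.floor(rank)), int(np.ceil(rank))
    p90 = v[lo] + (rank - lo) * (v[hi] - v[lo])
    thr = factor * p90
    return thr, 100.0 * np.sum(v < thr) / v.size


class TestVDP:
    def test_ninety_ten_split(self):
        rvent = np.concatenate([np.full(90, 1.0), np.full(10, 0.1)])
        mask = LungMask(np.ones((10, 10), bool))
        thr, vdp = vdp_rvent(rvent.reshape(10, 10), mask)
        assert thr == pytest.approx(0.4)
        assert vdp == pytest.approx(10.0)

    def test_constant_positive_map_has_no_defects(self):
        mask = LungMask(np.ones((10, 10), bool))
        thr, vdp = vdp_rvent(np.full((10, 10), 0.3), mask)
        assert vdp == 0.0

    def test_all_zero_map_warns_full_defect(self):
        mask = LungMask(np.ones((10, 10), bool))
        with pytest.warns(UserWarning):
            _, vdp = vdp_rvent(np.zeros((10, 10)), mask)
        assert vdp == 100.0

    @pytest.mark.parametrize("n", [100, 1000, 9973])
    def test_matches_brute_force_oracle(self, n, rng):
        vals = rng.lognormal(0.0, 0.6, size=n)
        side = int(np.ceil(np.sqrt(n)))
        grid = np.zeros((side, side))
        mask = np.zeros((side, side), bool)
        grid.flat[:n], mask.flat[:n] = vals, True
        thr, vdp = vdp_rvent(grid, LungMask(mask))
        thr_o, vdp_o = _brute_force_vdp(vals)
        assert thr == pytest.approx(thr_o, rel=1e-12)
        assert vdp == pytest.approx(vdp_o, abs=1e-12)


class TestReferenceLoop:
    def test_homogeneous_phantom_reference_matches_single_voxel(self):
        p = PhantomParams(grid_size=64, amplitude_cv=0.0, perfusion_amplitude=0.0, seed=2)
        series, truth = synthesize_series(p)
        mask = LungMask(truth.lung_mask)
        phases = estimate_phase(series, mask)
        cycle = sort_to_cycle(series, phases, mask)
        rvent, _ = compute_rvent(cycle, mask)
        ref = build_reference_fvl(cycle, rvent, mask)
        from prefulvent.core import _voxel_loops

        vol, flow = _voxel_loops(cycle, mask.lung)
        assert np.allclose(ref.volume, vol[0], rtol=0.01, atol=1e-4)
        assert np.allclose(ref.flow, flow[0], rtol=0.01, atol=1e-3)

    def test_percentile_band_rank_selection(self):
        """RVent values 1..100 -> selected voxels are exactly the (75,95]
        rank band under linear-interpolation percentiles."""
        vals = np.arange(1.0, 101.0)
        mask = LungMask(np.ones((10, 10), bool))
        n_bins = 12
        sig = np.ones((10, 10, n_bins)) * np.linspace(100, 80, n_bins)[None, None, :]
        centers = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
        cycle = PhaseResolvedCycle(sig, centers, np.ones(n_bins, int), n_bins - 1, 0, n_bins // 2)
        ref = build_reference_fvl(cycle, vals.reshape(10, 10), mask)
        # brute-force rank selection: P75 = 75.25, P95 = 95.05 -> values 76..95
        assert ref.n_selected == 20

    def test_all_equal_rvent_selects_everything(self):
        values = np.linspace(100, 80, 12)
        cycle, mask = _uniform_cycle(values, mask_shape=(12, 12))
        ref = build_reference_fvl(cycle, np.full((12, 12), 0.2), mask)
        assert ref.n_selected == mask.area


class TestFVL:
    def test_identical_loop_scores_100(self):
        # in a homogeneous phantom every voxel's loop equals the reference
        p = PhantomParams(grid_size=64, amplitude_cv=0.0, perfusion_amplitude=0.0, seed=2)
        series, truth = synthesize_series(p)
        mask = LungMask(truth.lung_mask)
        phases = estimate_phase(series, mask)
        cycle = sort_to_cycle(series, phases, mask)
        rvent, _ = compute_rvent(cycle, mask)
        ref = build_reference_fvl(cycle, rvent, mask)
        fvl = fvl_cc_map(cycle, ref, mask)
        assert np.all(fvl.cc[mask.lung] >= 99.5)
        assert fvl.vdp_fvl == 0.0

    def test_negated_flow_reference_scores_zero(self):
        """Against a reference whose flow limb is negated, a loop identical
        in volume anti-correlates on the flow half: the serialized
        correlation averages volume (+1) and flow (-1) to zero, clipped."""
        n_bins = 12
        centers = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
        base = 100.0 * (1 - 0.2 * (1 - np.cos(centers)) / 2)
        mask = LungMask(np.ones((16, 16), bool))
        sig = np.ones((16, 16, n_bins)) * base[None, None, :]
        cycle = PhaseResolvedCycle(
            sig, centers, np.ones(n_bins, int),
            int(np.argmin(base)), int(np.argmax(base)), n_bins // 4,
        )
        rvent, _ = compute_rvent(cycle, mask)
        ref = build_reference_fvl(cycle, rvent, mask)
        fvl_same = fvl_cc_map(cycle, ref, mask)
        assert np.all(fvl_same.cc[mask.lung] == pytest.approx(100.0))
        from prefulvent.core import ReferenceLoop

        flipped = ReferenceLoop(ref.volume, -ref.flow, ref.n_selected)
        fvl_flip = fvl_cc_map(cycle, flipped, mask)
        assert np.all(np.abs(fvl_flip.cc[mask.lung]) <= 1e-9)

    def test_zero_variance_voxel_counted(self):
        values = np.linspace(100, 80, 12)
        cycle, mask = _uniform_cycle(values, mask_shape=(12, 12))
        cycle.signal[0, 0, :] = 100.0  # non-ventilated voxel
        rvent, _ = compute_rvent(cycle, mask)
        ref = build_reference_fvl(cycle, rvent, mask)
        fvl = fvl_cc_map(cycle, ref, mask)
        assert fvl.n_zero_variance == 1
        assert fvl.cc[0, 0] == 0.0

    def test_shift_search_forgives_phase_lag(self):
        p = PhantomParams(grid_size=64, lag_fraction=0.15, seed=3)
        series, truth = synthesize_series(p)
        mask = LungMask(truth.lung_mask)
        from prefulvent.preprocess import lowpass_filter

        filtered = lowpass_filter(series)
        phases = estimate_phase(filtered, mask)
        cycle = sort_to_cycle(filtered, phases, mask)
        rvent, _ = compute_rvent(cycle, mask)
        ref = build_reference_fvl(cycle, rvent, mask)
        strict = fvl_cc_map(cycle, ref, mask, shift_search=False)
        lenient = fvl_cc_map(cycle, ref, mask, shift_search=True)
        assert strict.vdp_fvl > lenient.vdp_fvl
        assert lenient.cc[truth.lag_mask].mean() > strict.cc[truth.lag_mask].mean()


class TestScaleInvariance:
    @pytest.mark.parametrize("factor", [0.5, 3.0, 1e4])
    def test_maps_invariant_under_global_rescale(self, small_phantom, factor):
        from prefulvent import analyze_series

        series, truth = small_phantom
        base = analyze_series(series, truth.lung_mask)
        scaled = analyze_series(series.with_signal(series.signal * factor), truth.lung_mask)
        assert scaled.rvent.vdp_rvent == pytest.approx(base.rvent.vdp_rvent, abs=1e-9)
        assert scaled.fvl.vdp_fvl == pytest.approx(base.fvl.vdp_fvl, abs=1e-9)
        assert np.allclose(scaled.rvent.rvent, base.rvent.rvent, rtol=1e-9, atol=1e-12)
        assert np.allclose(scaled.fvl.cc, base.fvl.cc, rtol=1e-9, atol=1e-6)
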