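"""Phase-resolved ventilation analysis.

Given a perfusion-suppressed dynamic series and a lung mask, this module
(i) estimates a respiratory phase for every frame from a cosine model of the
spatially averaged lung signal, (ii) sorts frames into one composite
phase-resolved respiratory cycle, (iii) derives a regional-ventilation map

    RVent(x, y) = S_Mid / S_Insp  -  S_Mid / S_Exp

from the signal at the mid, end-inspiratory and end-expiratory states, with
a ventilation defect percentage (VDP) below an adaptive threshold of
0.4 times the 90th-percentile RVent, and (iv) builds per-voxel signal-derived
flow-volume loops, correlates them with a healthy reference loop averaged
over the 75th-95th RVent percentile band, and reports the percentage of
voxels whose loop correlation falls below 90% (FVL VDP).

Phase convention: phase 0 at end-expiration (signal maximum), phase pi at
end-inspiration (signal minimum) — the proton-density signal falls as the
lung inflates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .exceptions import InsufficientSamplingError, InvalidParameterError, PhaseEstimationError
from .series import DynamicSeries, LungMask

DEFAULT_N_BINS = 15
VDP_FACTOR = 0.4
VDP_PERCENTILE = 90.0
FVL_BAND = (75.0, 95.0)
FVL_CUTOFF = 90.0
MIN_FIT_QUALITY = 0.2


# ---------------------------------------------------------------- phase ---

@dataclass
class PhaseAssignment:
    phase_per_frame: np.ndarray  # radians in [0, 2pi)
    respiratory_frequency: float  # Hz
    fit_quality: float  # fraction of mean-signal variance explained


def _cosine_sse(freq: float, t: np.ndarray, m: np.ndarray) -> float:
    """Residual sum of squares of the best-fitting C + A*cos(2pi f t - psi)."""
    design = np.column_stack(
        [np.ones_like(t), np.cos(2 * math.pi * freq * t), np.sin(2 * math.pi * freq * t)]
    )
    _, res, _, _ = np.linalg.lstsq(design, m, rcond=None)
    if res.size:
        return float(res[0])
    fit = design @ np.linalg.lstsq(design, m, rcond=None)[0]
    return float(np.sum((m - fit) ** 2))


def estimate_phase(
    series: DynamicSeries,
    mask: LungMask,
    cutoff_hz: float = 0.7,
    window_periods: float = 2.0,
) -> PhaseAssignment:
    """Assign a respiratory phase to every frame.

    The respiratory frequency is the dominant spectral peak of the
    spatial-mean in-lung signal below the filter cutoff, refined by
    minimizing the cosine-fit residual over a bracket of one FFT bin.
    Per-frame phases come from a sliding-window cosine fit (window of about
    two periods) so slow drift of the breathing period is tracked.
    """
    m = series.mean_signal(mask.lung)
    t = series.frame_times
    sst = float(np.sum((m - m.mean()) ** 2))
    if sst < 1e-12:
        raise PhaseEstimationError("constant in-lung signal: no respiration present")

    demeaned = m - m.mean()
    freqs = np.fft.rfftfreq(m.size, series.frame_interval)
    power = np.abs(np.fft.rfft(demeaned)) ** 2
    band = (freqs > 0) & (freqs < cutoff_hz)
    if not band.any():
        raise PhaseEstimationError("no spectral band below cutoff")
    coarse = freqs[band][np.argmax(power[band])]
    dfreq = freqs[1] - freqs[0]
    lo = max(coarse - dfreq, dfreq / 4)
    hi = min(coarse + dfreq, cutoff_hz)
    res = optimize.minimize_scalar(
        _cosine_sse, bounds=(lo, hi), args=(t, m), method="bounded",
        options={"xatol": 1e-6},
    )
    freq = float(res.x)

    omega = 2 * math.pi * freq
    half = max(int(round(window_periods / freq / series.frame_interval / 2)), 3)
    n = m.size
    phases = np.empty(n)
    fitted = np.empty(n)
    cos_t, sin_t = np.cos(omega * t), np.sin(omega * t)
    for i in range(n):
        a, b = max(0, i - half), min(n, i + half + 1)
        design = np.column_stack([np.ones(b - a), cos_t[a:b], sin_t[a:b]])
        coef, _, _, _ = np.linalg.lstsq(design, m[a:b], rcond=None)
        c0, bc, bs = coef
        psi = math.atan2(bs, bc)  # m ~ c0 + A cos(omega t - psi), A >= 0
        phases[i] = (omega * t[i] - psi) % (2 * math.pi)
        fitted[i] = c0 + bc * cos_t[i] + bs * sin_t[i]

    quality = float(np.clip(1.0 - np.sum((m - fitted) ** 2) / sst, 0.0, 1.0))
    if quality < MIN_FIT_QUALITY:
        raise PhaseEstimationError(
            f"cosine model explains only {quality:.2f} of mean-signal variance"
        )
    return PhaseAssignment(phases, freq, quality)


# ---------------------------------------------------------------- cycle ---

@dataclass
class PhaseResolvedCycle:
    """One composite respiratory cycle: voxelwise mean signal per phase bin."""

    signal: np.ndarray  # (ny, nx, n_bins)
    bin_centers: np.ndarray  # radians
    bin_counts: np.ndarray  # frames contributing per bin
    idx_insp: int  # end-inspiration (minimum mean lung signal)
    idx_exp: int  # end-expiration (maximum mean lung signal)
    idx_mid: int  # midway along the inspiratory limb
    n_merged: int = 0

    @property
    def n_bins(self) -> int:
        return self.signal.shape[2]


def sort_to_cycle(
    series: DynamicSeries,
    phases: PhaseAssignment,
    mask: LungMask,
    n_bins: int = DEFAULT_N_BINS,
) -> PhaseResolvedCycle:
    """Bin frames by respiratory phase into one high-resolution cycle.

    Frames fall into ``n_bins`` equal-width phase bins; each bin stores the
    voxelwise mean of its frames. Empty bins (allowed up to 30% of bins)
    inherit the signal of the circularly nearest occupied bin.
    """
    if n_bins < 10:
        raise InvalidParameterError("n_bins must be >= 10")
    phi = phases.phase_per_frame % (2 * math.pi)
    idx = np.minimum((phi / (2 * math.pi) * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    n_empty = int((counts == 0).sum())
    if n_empty > 0.3 * n_bins:
        raise InsufficientSamplingError(
            f"{n_empty}/{n_bins} phase bins are empty: phase coverage insufficient"
        )
    ny, nx, _ = series.signal.shape
    cyc = np.zeros((ny, nx, n_bins))
    for b in range(n_bins):
        if counts[b]:
            cyc[:, :, b] = series.signal[:, :, idx == b].mean(axis=2)
    out_counts = counts.copy()
    if n_empty:
        occupied = np.where(counts > 0)[0]
        for b in np.where(counts == 0)[0]:
            d = np.abs(occupied - b)
            d = np.minimum(d, n_bins - d)
            src = occupied[np.argmin(d)]
            cyc[:, :, b] = cyc[:, :, src]
            out_counts[b] = counts[src]

    centers = (np.arange(n_bins) + 0.5) * 2 * math.pi / n_bins
    mean_per_bin = cyc[mask.lung].mean(axis=0)
    idx_insp = int(np.argmin(mean_per_bin))
    idx_exp = int(np.argmax(mean_per_bin))
    # midway in phase along the inspiratory limb (exp -> insp, increasing phase)
    fwd = (centers[idx_insp] - centers[idx_exp]) % (2 * math.pi)
    mid_phase = (centers[idx_exp] + fwd / 2.0) % (2 * math.pi)
    d = np.abs(centers - mid_phase)
    idx_mid = int(np.argmin(np.minimum(d, 2 * math.pi - d)))
    return PhaseResolvedCycle(cyc, centers, out_counts, idx_insp, idx_exp, idx_mid, n_empty)


# ---------------------------------------------------------------- RVent ---

@dataclass
class RVentMap:
    rvent: np.ndarray  # (ny, nx), zero outside the lung
    threshold: float
    vdp_rvent: float  # percent
    n_repaired: int = 0


def compute_rvent(cycle: PhaseResolvedCycle, mask: LungMask) -> tuple[np.ndarray, int]:
    """Regional ventilation: S_Mid/S_Insp - S_Mid/S_Exp per lung voxel.

    Voxels with a non-positive end-state signal are set to 0; the count is
    returned alongside the map.
    """
    s_mid = cycle.signal[:, :, cycle.idx_mid]
    s_insp = cycle.signal[:, :, cycle.idx_insp]
    s_exp = cycle.signal[:, :, cycle.idx_exp]
    rvent = np.zeros(mask.lung.shape)
    lung = mask.lung
    bad = lung & ((s_insp <= 0) | (s_exp <= 0))
    ok = lung & ~bad
    rvent[ok] = s_mid[ok] / s_insp[ok] - s_mid[ok] / s_exp[ok]
    return rvent, int(bad.sum())


def vdp_rvent(
    rvent: np.ndarray,
    mask: LungMask,
    factor: float = VDP_FACTOR,
    percentile: float = VDP_PERCENTILE,
) -> tuple[float, float]:
    """Adaptive-threshold ventilation defect percentage.

    threshold = factor x (90th percentile of in-mask RVent); the VDP is the
    percentage of lung voxels strictly below it (voxels exactly at the
    threshold count as normal).
    """
    vals = rvent[mask.lung]
    if vals.size < 100:
        raise InvalidParameterError("need >= 100 lung voxels")
    if np.all(vals == 0):
        warnings.warn("all-zero RVent map: VDP set to 100%")
        return 0.0, 100.0
    threshold = factor * float(np.percentile(vals, percentile))
    vdp = 100.0 * float(np.mean(vals < threshold))
    return threshold, vdp


def rvent_map(cycle: PhaseResolvedCycle, mask: LungMask, **kwargs) -> RVentMap:
    """Convenience wrapper: RVent map with its adaptive-threshold VDP."""
    rvent, n_repaired = compute_rvent(cycle, mask)
    threshold, vdp = vdp_rvent(rvent, mask, **kwargs)
    return RVentMap(rvent, threshold, vdp, n_repaired)


# ------------------------------------------------------------------ FVL ---

@dataclass
class ReferenceLoop:
    """Healthy reference flow-volume loop over the phase bins."""

    volume: np.ndarray  # (n_bins,)
    flow: np.ndarray  # (n_bins,)
    n_selected: int


@dataclass
class FVLMap:
    cc: np.ndarray  # (ny, nx), percent in [0, 100], zero outside the lung
    reference: ReferenceLoop
    vdp_fvl: float  # percent
    n_zero_variance: int = 0


def _voxel_loops(cycle: PhaseResolvedCycle, lung: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel volume proxy V(phi) = S(phi)/S(exp) - 1 and flow proxy
    F(phi) = circular central difference of V over phase."""
    sig = cycle.signal[lung]  # (n_vox, n_bins)
    s_exp = sig[:, cycle.idx_exp][:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        vol = np.where(s_exp > 0, sig / s_exp - 1.0, 0.0)
    dphi = 2 * math.pi / cycle.n_bins
    flow = (np.roll(vol, -1, axis=1) - np.roll(vol, 1, axis=1)) / (2 * dphi)
    return vol, flow


def build_reference_fvl(
    cycle: PhaseResolvedCycle,
    rvent: np.ndarray,
    mask: LungMask,
    band: tuple[float, float] = FVL_BAND,
) -> ReferenceLoop:
    """Average loop over voxels whose RVent lies in the healthy percentile band.

    Selecting the 75th-95th percentile band excludes both hypoventilated and
    excessively ventilated regions; if the band collapses (all-equal RVent),
    every voxel is selected.
    """
    vals = rvent[mask.lung]
    if vals.size < 100:
        raise InvalidParameterError("need >= 100 lung voxels")
    p_lo, p_hi = np.percentile(vals, band)
    sel = (vals >= p_lo) & (vals <= p_hi)
    if not sel.any():
        raise InvalidParameterError("empty reference selection")
    vol, flow = _voxel_loops(cycle, mask.lung)
    return ReferenceLoop(vol[sel].mean(axis=0), flow[sel].mean(axis=0), int(sel.sum()))


def _standardize(x: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    ok = sd[..., 0] > 1e-12
    z = np.where(sd > 1e-12, (x - mu) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    return z, ok


def fvl_cc_map(
    cycle: PhaseResolvedCycle,
    reference: ReferenceLoop,
    mask: LungMask,
    cutoff: float = FVL_CUTOFF,
    shift_search: bool = False,
) -> FVLMap:
    """Correlate every voxel's flow-volume loop with the reference loop.

    The loop is serialized as volume-then-flow, each segment standardized to
    zero mean and unit variance; the correlation of the concatenation with
    the reference's is reported in percent, clipped below at zero. By default
    the loops are compared at zero phase shift, so regions that empty with a
    phase lag score a low correlation — the pathological signature the map is
    designed to expose. ``shift_search=True`` instead maximizes over circular
    integer bin shifts, which forgives pure timing differences.

    The FVL VDP is the percentage of lung voxels with correlation below
    ``cutoff`` (default 90%). Zero-variance loops score 0 and are counted.
    """
    vol, flow = _voxel_loops(cycle, mask.lung)
    zv, okv = _standardize(vol)
    zf, okf = _standardize(flow)
    zrv, okr1 = _standardize(reference.volume[None, :])
    zrf, okr2 = _standardize(reference.flow[None, :])
    if not (okr1[0] and okr2[0]):
        raise InvalidParameterError("reference loop has zero variance")
    n_bins = cycle.n_bins
    ok = okv & okf

    def corr(zv_s: np.ndarray, zf_s: np.ndarray) -> np.ndarray:
        # Pearson of the concatenated standardized segments
        return 0.5 * ((zv_s * zrv).mean(axis=1) + (zf_s * zrf).mean(axis=1))

    if shift_search:
        best = np.full(vol.shape[0], -np.inf)
        for s in range(n_bins):
            best = np.maximum(best, corr(np.roll(zv, s, axis=1), np.roll(zf, s, axis=1)))
        rho = best
    else:
        rho = corr(zv, zf)
    cc_vals = np.clip(rho, 0.0, 1.0) * 100.0
    cc_vals[~ok] = 0.0
    cc = np.zeros(mask.lung.shape)
    cc[mask.lung] = cc_vals
    vdp = 100.0 * float(np.mean(cc_vals < cutoff))
    return FVLMap(cc, reference, vdp, int((~ok).sum()))
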