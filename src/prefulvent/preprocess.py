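"""Bring a raw dynamic series to analysis-ready form.

Stages: optional rigid registration to a mid-respiratory reference frame,
classical lung segmentation from the temporal-mean image, vessel removal by
Otsu thresholding, and zero-phase temporal low-pass filtering to suppress
the cardiac/perfusion signal while preserving the respiratory band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, opening, remove_small_objects
from skimage.registration import phase_cross_correlation

from .exceptions import InvalidParameterError, SegmentationError
from .series import DynamicSeries, LungMask

DEFAULT_CUTOFF_HZ = 0.7


@dataclass
class RegistrationReport:
    """Per-frame translation applied during rigid registration."""

    displacements: np.ndarray  # (n_frames, 2) in pixels, (row, col)
    reference_frame: int
    n_failed: int = 0
    warnings: list[str] | None = None

    @property
    def max_displacement(self) -> float:
        return float(np.abs(self.displacements).max())


def _reference_frame_index(series: DynamicSeries, mask: np.ndarray | None) -> int:
    """Frame whose spatial-mean signal is closest to the temporal median —
    an intermediate respiratory position."""
    m = series.mean_signal(mask)
    return int(np.argmin(np.abs(m - np.median(m))))


def register_series(
    series: DynamicSeries,
    mode: str = "none",
    mask: np.ndarray | None = None,
    upsample_factor: int = 10,
    max_shift_px: float = 20.0,
) -> tuple[DynamicSeries, RegistrationReport]:
    """Translation-only registration of every frame to a mid-position reference.

    ``mode='none'`` returns the input unchanged with zero displacements.
    ``mode='rigid'`` estimates per-frame translation by phase cross-correlation
    against the reference frame and resamples each frame accordingly. Frames
    whose estimated shift exceeds ``max_shift_px`` count as failures; if more
    than 10% of frames fail, the result carries a warning rather than raising.
    """
    if mode not in ("none", "rigid"):
        raise InvalidParameterError(f"unknown registration mode {mode!r}")
    ref_idx = _reference_frame_index(series, mask)
    n = series.n_frames
    disp = np.zeros((n, 2))
    if mode == "none":
        return series, RegistrationReport(disp, ref_idx)

    ref = series.signal[:, :, ref_idx]
    out = np.empty_like(series.signal)
    n_failed = 0
    for i in range(n):
        frame = series.signal[:, :, i]
        if i == ref_idx:
            out[:, :, i] = frame
            continue
        shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=upsample_factor)
        if np.abs(shift).max() > max_shift_px:
            n_failed += 1
            out[:, :, i] = frame
            continue
        disp[i] = shift
        out[:, :, i] = ndimage.shift(frame, shift, order=1, mode="nearest")
    np.clip(out, 0.0, None, out=out)
    warns = []
    if n_failed > 0.10 * n:
        warns.append(f"registration failed on {n_failed}/{n} frames")
        warnings.warn(warns[-1])
    return series.with_signal(out), RegistrationReport(disp, ref_idx, n_failed, warns or None)


def segment_lungs(
    series: DynamicSeries,
    min_area: int = 100,
    truth_mask: np.ndarray | None = None,
) -> LungMask:
    """Segment the lungs from the temporal-mean image.

    Classical fallback: the lungs are the low-intensity regions *enclosed* by
    the bright body tissue. The body is thresholded by Otsu on the mean image,
    its holes filled; the holes (dark interior regions) are cleaned by
    morphology and the largest two components kept. ``truth_mask`` bypasses
    segmentation entirely (masks are inputs in real use).
    """
    if truth_mask is not None:
        return LungMask(np.asarray(truth_mask, bool))
    mean_img = series.signal.mean(axis=2)
    if np.ptp(mean_img) < 1e-9:
        raise SegmentationError("uniform image: no contrast to segment")
    thr = threshold_otsu(mean_img, nbins=256)
    body = mean_img > thr
    body = remove_small_objects(body, max_size=63)
    filled = ndimage.binary_fill_holes(body)
    interior = filled & ~body
    interior = opening(interior, disk(1))
    interior = closing(interior, disk(2))
    interior = remove_small_objects(interior, max_size=min_area // 4 - 1)
    labels, n = ndimage.label(interior)
    if n == 0 or interior.sum() < min_area:
        raise SegmentationError("segmentation produced an empty lung mask")
    warns = []
    if n < 2:
        warns.append("single lung component found")
        warnings.warn(warns[-1])
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:2] + 1
    mask = np.isin(labels, keep)
    return LungMask(mask, warnings=warns)


def remove_vessels(mask: LungMask, series: DynamicSeries, nbins: int = 256) -> LungMask:
    """Strip bright vascular voxels from the lung mask.

    An Otsu threshold over a 256-bin histogram of the temporal-mean
    intensities inside the mask separates the bright vessel class, which is
    removed. A degenerate (near-constant) histogram leaves the mask
    unchanged; emptying the mask entirely is an error.
    """
    mean_img = series.signal.mean(axis=2)
    vals = mean_img[mask.lung]
    if vals.size == 0:
        raise SegmentationError("cannot remove vessels from an empty mask")
    if np.ptp(vals) < 1e-9:
        return LungMask(mask.lung.copy(), vessels_removed=True, warnings=list(mask.warnings))
    thr = threshold_otsu(vals, nbins=nbins)
    new = mask.lung & ~(mean_img > thr)
    if new.sum() == 0:
        raise SegmentationError("vessel removal emptied the lung mask")
    if new.sum() < 0.5 * mask.lung.sum():
        # near-unimodal histogram: Otsu split would discard most of the lung
        warnings.warn("vessel removal would remove >=50% of the mask; skipped")
        return LungMask(mask.lung.copy(), vessels_removed=True, warnings=list(mask.warnings))
    return LungMask(new, vessels_removed=True, warnings=list(mask.warnings))


def lowpass_filter(
    series: DynamicSeries,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = 5,
    check_bands: bool = False,
) -> DynamicSeries:
    """Zero-phase Butterworth low-pass along the frame axis of every voxel.

    The default cutoff (0.7 Hz) sits between typical respiratory (~0.2-0.4 Hz)
    and cardiac (~1 Hz) spectral peaks: respiratory content passes with gain
    >= 0.99 while the cardiac/perfusion oscillation is attenuated to <= 5%.
    With ``check_bands`` the mean-signal spectrum is inspected and a warning
    issued if the two dominant peaks do not bracket the cutoff.
    """
    nyq = series.sampling_rate / 2.0
    if cutoff_hz >= nyq:
        raise InvalidParameterError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq:.3f} Hz")
    if check_bands:
        _warn_if_peaks_do_not_bracket(series, cutoff_hz)
    sos = sps.butter(order, cutoff_hz, btype="low", fs=series.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, series.signal, axis=2)
    np.clip(filtered, 0.0, None, out=filtered)
    return series.with_signal(filtered)


def _warn_if_peaks_do_not_bracket(series: DynamicSeries, cutoff_hz: float) -> None:
    m = series.mean_signal()
    m = m - m.mean()
    freqs = np.fft.rfftfreq(m.size, series.frame_interval)
    power = np.abs(np.fft.rfft(m)) ** 2
    lo, hi = freqs < cutoff_hz, freqs >= cutoff_hz
    lo[0] = False
    floor = power.mean()
    has_resp = lo.any() and power[lo].max() > 10 * floor
    has_card = hi.any() and power[hi].max() > 2 * floor
    if not (has_resp and has_card):
        warnings.warn(
            "estimated respiratory/cardiac spectral peaks do not bracket "
            f"the cutoff {cutoff_hz} Hz"
        )
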