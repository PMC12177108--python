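"""Synthetic free-breathing lung-MRI phantoms with known ventilation structure.

The phantom emulates the signal physics that phase-resolved ventilation
mapping exploits: lung parenchyma signal falls on inspiration (proton-density
dilution as the lung inflates) and rises on expiration. Each lung voxel
oscillates as

    S(x, y, t) = S0 * [1 - a(x,y) * (1 - cos(phi(t) - lag(x,y))) / 2]
                    * [1 + p(x,y) * sin(2 pi f_card t)]  + noise

where ``a`` is the fractional ventilation-amplitude map (near zero inside
programmed defect regions), ``phi`` the respiratory phase trace, ``lag`` a
per-voxel phase lag modelling delayed regional emptying, and the second
bracket a faster perfusion oscillation at the cardiac frequency. The signal
is maximal at end-expiration (phase 0) and minimal at end-inspiration
(phase pi).

Ventilation heterogeneity has two programmable sources: binary defect/lag
regions, and a smooth multiplicative lognormal amplitude field whose
coefficient of variation (``amplitude_cv``) produces the continuous spread
of regional ventilation seen in real lungs.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .exceptions import InvalidParameterError
from .series import DynamicSeries

TISSUE_INTENSITY = 300.0
LUNG_BASELINE = 100.0
VESSEL_INTENSITY = 450.0


@dataclass
class LungGeometry:
    """Fractional geometry of the two elliptical lungs inside a torso."""

    centers: tuple[tuple[float, float], tuple[float, float]] = (
        (0.50, 0.32),
        (0.50, 0.68),
    )
    semi_axes: tuple[float, float] = (0.30, 0.14)  # (row, column) fractions
    torso_semi_axes: tuple[float, float] = (0.46, 0.42)


@dataclass
class PhantomParams:
    """Parameters of one synthetic acquisition.

    Defaults mirror a typical single-slice tidal-breathing protocol:
    128 x 128 matrix, 250 frames at 135 ms/frame (~34 s), a 4 s respiratory
    period and a 1.1 Hz cardiac frequency.
    """

    grid_size: int = 128
    n_frames: int = 250
    frame_interval: float = 0.135
    respiratory_period: float = 4.0
    period_jitter_cv: float = 0.0
    cardiac_frequency: float = 1.1
    ventilation_amplitude: float = 0.2
    amplitude_cv: float = 0.10
    defect_fraction: float = 0.0
    defect_amplitude_factor: float = 0.0
    lag_fraction: float = 0.0
    lag_radians: float = math.pi / 2
    perfusion_amplitude: float = 0.05
    noise_sd: float = 0.0
    noise_model: str = "gaussian"
    drift_px: float = 0.0
    vessel_fraction: float = 0.0
    seed: int = 0
    geometry: LungGeometry = field(default_factory=LungGeometry)

    def __post_init__(self) -> None:
        if self.grid_size < 32:
            raise InvalidParameterError("grid_size must be >= 32")
        if self.defect_fraction < 0 or self.lag_fraction < 0:
            raise InvalidParameterError("fractions must be non-negative")
        if self.defect_fraction + self.lag_fraction > 1:
            raise InvalidParameterError("defect_fraction + lag_fraction must be <= 1")
        if not (0 <= self.ventilation_amplitude < 1):
            raise InvalidParameterError("ventilation_amplitude must be in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.perfusion_amplitude < 0 or self.amplitude_cv < 0:
            raise InvalidParameterError("amplitudes must be non-negative")
        if self.respiratory_period <= 2 * self.frame_interval:
            raise InvalidParameterError(
                "respiratory_period must exceed twice the frame interval "
                "(breathing would alias)"
            )
        if self.noise_model not in ("gaussian", "rician"):
            raise InvalidParameterError("noise_model must be 'gaussian' or 'rician'")


@dataclass
class PhantomTruth:
    """Ground truth saved alongside a synthetic series."""

    amplitude_map: np.ndarray
    defect_mask: np.ndarray
    lag_mask: np.ndarray
    lag_map: np.ndarray
    phase_trace: np.ndarray
    lung_mask: np.ndarray
    vessel_mask: np.ndarray
    respiratory_frequency: float


def make_lung_mask(grid_size: int, geometry: LungGeometry | None = None) -> np.ndarray:
    """Two simply connected elliptical lung regions on a square grid."""
    if grid_size < 32:
        raise InvalidParameterError("grid_size must be >= 32")
    geometry = geometry or LungGeometry()
    ay, ax = geometry.semi_axes
    if ay <= 0 or ax <= 0:
        raise InvalidParameterError("lung semi-axes must be positive")
    yy, xx = np.mgrid[0:grid_size, 0:grid_size]
    mask = np.zeros((grid_size, grid_size), dtype=bool)
    for cy, cx in geometry.centers:
        e = ((yy - cy * grid_size) / (ay * grid_size)) ** 2 + (
            (xx - cx * grid_size) / (ax * grid_size)
        ) ** 2
        mask |= e <= 1.0
    if not mask.any():
        raise InvalidParameterError("degenerate geometry: zero-area lungs")
    return mask


def make_torso_mask(grid_size: int, geometry: LungGeometry | None = None) -> np.ndarray:
    geometry = geometry or LungGeometry()
    ay, ax = geometry.torso_semi_axes
    yy, xx = np.mgrid[0:grid_size, 0:grid_size]
    c = grid_size / 2.0
    return ((yy - c) / (ay * grid_size)) ** 2 + ((xx - c) / (ax * grid_size)) ** 2 <= 1.0


def _blobby_subset(
    region: np.ndarray, count: int, rng: np.random.Generator, exclude: np.ndarray | None = None
) -> np.ndarray:
    """Pick ``count`` spatially clustered pixels inside ``region``.

    Ranks a Gaussian-smoothed noise field and takes the lowest ``count``
    values, which yields contiguous blob-like patches with an exact pixel
    count.
    """
    out = np.zeros_like(region, dtype=bool)
    if count <= 0:
        return out
    field_ = ndimage.gaussian_filter(
        rng.standard_normal(region.shape), sigma=region.shape[0] / 16.0
    )
    field_ = np.where(region, field_, np.inf)
    if exclude is not None:
        field_ = np.where(exclude, np.inf, field_)
    flat_idx = np.argsort(field_, axis=None, kind="stable")[:count]
    out.flat[flat_idx] = True
    return out


def _vessel_mask(lung: np.ndarray, count: int) -> np.ndarray:
    """Thin bright vertical streaks of exactly ``count`` pixels per request."""
    out = np.zeros_like(lung, dtype=bool)
    if count <= 0:
        return out
    labels, n = ndimage.label(lung)
    remaining = count
    for lab in range(1, n + 1):
        comp = labels == lab
        share = count // n if lab < n else remaining
        cols = np.where(comp.any(axis=0))[0]
        cmid = cols[len(cols) // 2]
        band = comp & (np.abs(np.arange(lung.shape[1])[None, :] - cmid) <= 1)
        rows, cs = np.where(band)
        take = min(share, rows.size)
        out[rows[:take], cs[:take]] = True
        remaining -= take
    return out


def _phase_trace(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Respiratory phase per frame in [0, 2pi), advancing at the programmed
    rate with optional per-cycle multiplicative period jitter."""
    n, dt = params.n_frames, params.frame_interval
    phases = np.empty(n)
    phi = 0.0
    period = params.respiratory_period
    if params.period_jitter_cv > 0:
        period = params.respiratory_period * max(
            0.2, 1.0 + params.period_jitter_cv * rng.standard_normal()
        )
    for i in range(n):
        phases[i] = phi % (2 * math.pi)
        nxt = phi + 2 * math.pi * dt / period
        if params.period_jitter_cv > 0 and nxt // (2 * math.pi) > phi // (2 * math.pi):
            period = params.respiratory_period * max(
                0.2, 1.0 + params.period_jitter_cv * rng.standard_normal()
            )
        phi = nxt
    return phases


def synthesize_series(params: PhantomParams) -> tuple[DynamicSeries, PhantomTruth]:
    """Generate one synthetic 2D+t acquisition and its ground truth."""
    rng = np.random.default_rng(params.seed)
    g = params.grid_size
    lung = make_lung_mask(g, params.geometry)
    torso = make_torso_mask(g, params.geometry)
    n_lung = int(lung.sum())

    n_defect = int(round(params.defect_fraction * n_lung))
    n_lag = int(round(params.lag_fraction * n_lung))
    defect = _blobby_subset(lung, n_defect, rng)
    lag_mask = _blobby_subset(lung, n_lag, rng, exclude=defect)
    n_vessel = int(round(params.vessel_fraction * n_lung))
    vessels = _vessel_mask(lung, n_vessel)

    # smooth multiplicative lognormal field -> continuous amplitude spread
    amp = np.zeros((g, g))
    if params.amplitude_cv > 0:
        smooth = ndimage.gaussian_filter(rng.standard_normal((g, g)), sigma=g / 16.0)
        smooth = smooth / max(smooth[lung].std(), 1e-12)
        amp[lung] = params.ventilation_amplitude * np.exp(
            params.amplitude_cv * smooth[lung] - 0.5 * params.amplitude_cv**2
        )
    else:
        amp[lung] = params.ventilation_amplitude
    amp[defect] *= params.defect_amplitude_factor
    np.clip(amp, 0.0, 0.95, out=amp)

    lag_map = np.zeros((g, g))
    lag_map[lag_mask] = params.lag_radians

    phases = _phase_trace(params, rng)
    t = np.arange(params.n_frames) * params.frame_interval

    base = np.zeros((g, g))
    base[torso] = TISSUE_INTENSITY
    base[lung] = LUNG_BASELINE
    base[vessels] = VESSEL_INTENSITY

    # ventilation modulation acts on parenchyma only (not vessels)
    mod_region = lung & ~vessels
    vent = 1.0 - amp[..., None] * (1.0 - np.cos(phases[None, None, :] - lag_map[..., None])) / 2.0
    card = 1.0 + params.perfusion_amplitude * np.sin(2 * math.pi * params.cardiac_frequency * t)
    signal = np.repeat(base[..., None], params.n_frames, axis=2)
    signal[mod_region] = (
        base[mod_region][:, None] * vent[mod_region] * card[None, :]
    )

    if params.drift_px > 0:
        shifts = np.linspace(0.0, params.drift_px, params.n_frames)
        for i in range(params.n_frames):
            signal[:, :, i] = ndimage.shift(
                signal[:, :, i], (0.0, shifts[i]), order=1, mode="nearest"
            )

    if params.noise_sd > 0:
        sd = params.noise_sd * LUNG_BASELINE
        if params.noise_model == "gaussian":
            signal = signal + sd * rng.standard_normal(signal.shape)
        else:
            signal = np.hypot(
                signal + sd * rng.standard_normal(signal.shape),
                sd * rng.standard_normal(signal.shape),
            )
    np.clip(signal, 0.0, None, out=signal)

    series = DynamicSeries(signal, t)
    truth = PhantomTruth(
        amplitude_map=amp,
        defect_mask=defect,
        lag_mask=lag_mask,
        lag_map=lag_map,
        phase_trace=phases,
        lung_mask=lung,
        vessel_mask=vessels,
        respiratory_frequency=1.0 / params.respiratory_period,
    )
    return series, truth


@dataclass
class CohortSubject:
    """One simulated participant with pre/post-bronchodilator acquisitions."""

    subject_id: str
    group: str
    params_pre: PhantomParams
    params_post: PhantomParams
    covariates: dict


def _draw_fraction(dist, rng: np.random.Generator) -> float:
    if np.isscalar(dist):
        return float(dist)
    lo, hi = dist
    return float(rng.uniform(lo, hi))


def make_cohort(
    n_healthy: int = 7,
    n_disease: int = 23,
    healthy_defect: float | Sequence[float] = (0.0, 0.03),
    disease_defect: float | Sequence[float] = (0.1, 0.4),
    bronchodilator_shrink_healthy: float = 1.0,
    bronchodilator_shrink_disease: float = 0.7,
    covariate_intercept: float = 95.0,
    covariate_slope: float = 180.0,
    covariate_noise_sd: float = 5.0,
    amplitude_cv_base: float = 0.10,
    amplitude_cv_per_defect: float = 0.8,
    base_params: PhantomParams | None = None,
    seed: int = 0,
) -> list[CohortSubject]:
    """Simulate a two-group pre/post-bronchodilator cohort.

    Healthy-like subjects draw small defect fractions, disease-like subjects
    larger ones; post-bronchodilator parameters shrink the defect and lag
    fractions by the group's shrink factor. A spirometry-like covariate
    (FEV1 percent of predicted) is a monotone decreasing linear function of
    the pre-bronchodilator defect fraction plus Gaussian noise. Amplitude
    heterogeneity scales with the defect fraction so diseased lungs also show
    wider continuous ventilation spread. A gas-trapping-style flag marks
    subjects whose defect fraction exceeds the cohort median.
    """
    if n_healthy < 1 or n_disease < 1:
        raise InvalidParameterError("each group needs at least one subject")
    rng = np.random.default_rng(seed)
    base = base_params or PhantomParams()
    subjects: list[CohortSubject] = []
    specs = [("healthy", healthy_defect, bronchodilator_shrink_healthy)] * n_healthy + [
        ("disease", disease_defect, bronchodilator_shrink_disease)
    ] * n_disease
    for i, (group, dist, shrink) in enumerate(specs):
        df_pre = _draw_fraction(dist, rng)
        df_post = df_pre * shrink
        lag_pre = base.lag_fraction
        fev1 = covariate_intercept - covariate_slope * df_pre
        if covariate_noise_sd > 0:
            fev1 += covariate_noise_sd * rng.standard_normal()
        sub_seed = int(rng.integers(0, 2**31 - 1))
        params_pre = replace(
            base,
            defect_fraction=df_pre,
            lag_fraction=lag_pre,
            amplitude_cv=amplitude_cv_base + amplitude_cv_per_defect * df_pre,
            seed=sub_seed,
        )
        params_post = replace(
            base,
            defect_fraction=df_post,
            lag_fraction=lag_pre * shrink,
            amplitude_cv=amplitude_cv_base + amplitude_cv_per_defect * df_post,
            seed=sub_seed,  # same anatomy pre/post: defect blobs shrink in place
        )
        subjects.append(
            CohortSubject(
                subject_id=f"S{i:03d}",
                group=group,
                params_pre=params_pre,
                params_post=params_post,
                covariates={
                    "fev1_pct": fev1,
                    "defect_fraction_pre": df_pre,
                    "defect_fraction_post": df_post,
                },
            )
        )
    median_df = float(np.median([s.covariates["defect_fraction_pre"] for s in subjects]))
    for s in subjects:
        s.covariates["gas_trapping"] = bool(s.covariates["defect_fraction_pre"] > median_df)
    return subjects
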