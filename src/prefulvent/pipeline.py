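"""End-to-end orchestration: the three pipeline entry points.

``analyze_series`` is the pure in-memory chain (register -> segment/mask ->
vessel removal -> low-pass -> phase sort -> RVent/VDP -> FVL/VDP ->
heterogeneity); ``run_simulate``/``run_analyze``/``run_cohort`` wrap it with
file IO and write the fully resolved configuration next to their outputs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, heterogeneity, io, phantom, preprocess
from .cohort import paired_compare, results_table, route_and_compare, spearman_family, stratify_binary
from .config import PipelineConfig
from .exceptions import InvalidParameterError
from .series import DynamicSeries, LungMask

METRIC_COLUMNS = ["vdp_rvent", "vdp_fvl", "iqd", "ihi", "skewness", "kurtosis", "n_used"]
HEADLINE_METRICS = ["vdp_rvent", "vdp_fvl", "iqd", "ihi"]


@dataclass
class SubjectResult:
    """All maps and scalar metrics for one analyzed series."""

    rvent: core.RVentMap
    fvl: core.FVLMap
    het: heterogeneity.HeterogeneityMetrics
    phases: core.PhaseAssignment
    cycle: core.PhaseResolvedCycle
    mask: LungMask
    registration: preprocess.RegistrationReport

    def metrics_row(self) -> dict:
        return {
            "vdp_rvent": self.rvent.vdp_rvent,
            "vdp_fvl": self.fvl.vdp_fvl,
            "iqd": self.het.iqd,
            "ihi": self.het.ihi,
            "skewness": self.het.skewness,
            "kurtosis": self.het.kurtosis,
            "n_used": self.het.n_used,
            "median_rvent": float(np.median(self.rvent.rvent[self.mask.lung])),
            "respiratory_frequency_hz": self.phases.respiratory_frequency,
            "phase_fit_quality": self.phases.fit_quality,
        }


def analyze_series(
    series: DynamicSeries,
    mask: np.ndarray | LungMask | None = None,
    config: PipelineConfig | None = None,
) -> SubjectResult:
    """Run the full single-subject ventilation analysis in memory."""
    cfg = config or PipelineConfig()
    series, reg = preprocess.register_series(series, mode=cfg.registration)
    if mask is None:
        lung = preprocess.segment_lungs(series)
    elif isinstance(mask, LungMask):
        lung = mask
    else:
        lung = LungMask(np.asarray(mask, bool))
    if cfg.remove_vessels and not lung.vessels_removed:
        lung = preprocess.remove_vessels(lung, series)
    filtered = preprocess.lowpass_filter(series, cfg.cutoff_hz, cfg.filter_order)
    phases = core.estimate_phase(filtered, lung, cutoff_hz=cfg.cutoff_hz)
    cycle = core.sort_to_cycle(filtered, phases, lung, n_bins=cfg.n_phase_bins)
    rmap = core.rvent_map(cycle, lung, factor=cfg.vdp_factor, percentile=cfg.vdp_percentile)
    ref = core.build_reference_fvl(cycle, rmap.rvent, lung, band=cfg.fvl_band)
    fvl = core.fvl_cc_map(
        cycle, ref, lung, cutoff=cfg.fvl_cutoff, shift_search=cfg.fvl_shift_search
    )
    het = heterogeneity.compute_heterogeneity(
        rmap.rvent[lung.lung], trim_percentile=cfg.trim_percentile
    )
    return SubjectResult(rmap, fvl, het, phases, cycle, lung, reg)


def analyze_phantom_subject(
    params: phantom.PhantomParams, config: PipelineConfig | None = None
) -> SubjectResult:
    """Synthesize a phantom and analyze it with its ground-truth mask."""
    series, truth = phantom.synthesize_series(params)
    return analyze_series(series, truth.lung_mask, config)


def analyze_cohort(
    subjects: list[phantom.CohortSubject], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Analyze every subject pre and post; returns the long-format cohort table."""
    rows = []
    for sub in subjects:
        for condition, params in (("pre", sub.params_pre), ("post", sub.params_post)):
            result = analyze_phantom_subject(params, config)
            row = {"subject": sub.subject_id, "group": sub.group, "condition": condition}
            row.update(result.metrics_row())
            row.update(sub.covariates)
            rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------- file API ---

def run_simulate(
    out_dir: str | Path,
    n_healthy: int = 2,
    n_disease: int = 2,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    **cohort_kwargs,
) -> Path:
    """Simulate a small cohort to disk: per-subject series + truth + cohort CSV."""
    cfg = config or PipelineConfig()
    if seed is not None:
        cfg.seed = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = phantom.make_cohort(n_healthy, n_disease, seed=cfg.seed, **cohort_kwargs)
    rows = []
    for sub in subjects:
        for condition, params in (("pre", sub.params_pre), ("post", sub.params_post)):
            series, truth = phantom.synthesize_series(params)
            stem = f"{sub.subject_id}_{condition}"
            io.write_series(series, out / f"{stem}_series.nii.gz")
            io.write_map(truth.lung_mask, out / f"{stem}_lung_mask.nii.gz")
            io.write_map(truth.amplitude_map, out / f"{stem}_amplitude.nii.gz")
            io.write_map(truth.defect_mask, out / f"{stem}_defect_mask.nii.gz")
            io.write_json(
                {
                    "params": {
                        k: v
                        for k, v in vars(params).items()
                        if isinstance(v, (int, float, str, bool))
                    },
                    "phase_trace": truth.phase_trace,
                    "respiratory_frequency": truth.respiratory_frequency,
                },
                out / f"{stem}_truth.json",
            )
            rows.append(
                {"subject": sub.subject_id, "group": sub.group, "condition": condition}
                | sub.covariates
            )
    io.write_csv(pd.DataFrame(rows), out / "cohort.csv")
    cfg.to_yaml(out / "config_resolved.yaml")
    return out


def run_analyze(
    series_path: str | Path,
    mask_path: str | Path | None,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> Path:
    """Analyze one series from disk; writes maps, metrics CSV and a report."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    series = io.read_series(series_path)
    mask = io.read_mask(mask_path) if mask_path else None
    result = analyze_series(series, mask, cfg)
    io.write_map(result.rvent.rvent, out / "rvent.nii.gz")
    io.write_map(result.fvl.cc, out / "fvl_cc.nii.gz")
    io.write_map(result.mask.lung, out / "lung_mask.nii.gz")
    io.write_csv(pd.DataFrame([result.metrics_row()]), out / "metrics.csv")
    io.write_json(
        {
            "rvent_threshold": result.rvent.threshold,
            "rvent_repaired_voxels": result.rvent.n_repaired,
            "fvl_reference_n_selected": result.fvl.reference.n_selected,
            "fvl_zero_variance_voxels": result.fvl.n_zero_variance,
            "key_state_bins": {
                "end_inspiration": result.cycle.idx_insp,
                "end_expiration": result.cycle.idx_exp,
                "mid": result.cycle.idx_mid,
            },
            "merged_phase_bins": result.cycle.n_merged,
            "respiratory_frequency_hz": result.phases.respiratory_frequency,
            "phase_fit_quality": result.phases.fit_quality,
            "max_registration_displacement_px": result.registration.max_displacement,
            "wall_time_s": time.time() - t0,
        },
        out / "report.json",
    )
    cfg.to_yaml(out / "config_resolved.yaml")
    return out


def run_cohort(
    metrics_csv: str | Path,
    out_dir: str | Path,
    covariates_csv: str | Path | None = None,
    metrics: list[str] | None = None,
    covariate: str = "fev1_pct",
    flag_col: str | None = "gas_trapping",
) -> Path:
    """Run the statistical battery on a per-subject metrics table.

    Produces group comparisons (pre-bronchodilator), paired pre/post
    comparisons per group, Spearman correlations with Hochberg adjustment,
    and the binary stratification — as CSVs plus a markdown report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(metrics_csv)
    if covariates_csv:
        cov = pd.read_csv(covariates_csv)
        table = table.merge(cov, on=[c for c in ("subject", "condition") if c in cov.columns])
    metrics = metrics or [m for m in HEADLINE_METRICS if m in table.columns]
    groups = list(pd.unique(table["group"]))
    if len(groups) < 2:
        raise InvalidParameterError(
            "cohort statistics need two groups; metrics file contains only "
            f"{groups}"
        )
    pre = table[table["condition"] == "pre"]
    group_results = [route_and_compare(pre, m) for m in metrics]
    paired_results = []
    for g in groups:
        sub = table[table["group"] == g]
        for m in metrics:
            r = paired_compare(sub, m)
            r.metric = f"{g}:{m}"
            paired_results.append(r)
    spearman_results = (
        spearman_family(pre, metrics, covariate) if covariate in pre.columns else []
    )
    strat_results = (
        stratify_binary(pre, flag_col, metrics)
        if flag_col and flag_col in pre.columns
        else []
    )
    sections = {
        "group_comparison": results_table(group_results),
        "paired_pre_post": results_table(paired_results),
        "correlations": results_table(spearman_results) if spearman_results else pd.DataFrame(),
        "stratification": results_table(strat_results) if strat_results else pd.DataFrame(),
    }
    report = []
    for name, df in sections.items():
        if not df.empty:
            io.write_csv(df, out / f"{name}.csv")
            report.append(f"## {name.replace('_', ' ')}\n\n```\n{df.to_string(index=False)}\n```\n")
    io.atomic_write(out / "report.md", lambda p: p.write_text("\n".join(report)))
    return out
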