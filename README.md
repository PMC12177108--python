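# prefulvent

Phase-resolved functional lung MRI (PREFUL) ventilation analysis in Python:
from a free-breathing 2D+t proton-MRI series to regional-ventilation maps,
ventilation defect percentages, flow–volume-loop cross-correlation maps,
histogram heterogeneity metrics, and the cohort-level statistics of a
pre/post-bronchodilator study design.

PREFUL MRI derives regional lung function from an ordinary dynamic proton
acquisition during tidal breathing — no contrast gas, no breath-hold. The
parenchymal signal falls as the lung inflates (proton-density dilution) and
rises on expiration; sorting the acquired frames by respiratory phase turns
~35 s of free breathing into one composite, high-temporal-resolution
respiratory cycle from which ventilation maps are computed. The package is
aimed at pulmonary-imaging researchers who want an open, tested, scriptable
implementation of this analysis chain, and ships a seeded phantom generator
so every stage can be validated against known ground truth without patient
data.

## The method

Given the phase-resolved cycle signal `S(x, y, φ)` with identified
end-inspiratory, end-expiratory and mid states, regional ventilation is

    RVent(x, y) = S_Mid / S_Insp − S_Mid / S_Exp

The **RVent VDP** (ventilation defect percentage) is the percentage of lung
voxels below an adaptive threshold of 0.4 × the 90th percentile of the
in-mask RVent distribution. For the **FVL map**, each voxel's signal-derived
flow–volume loop (volume proxy `V(φ) = S(φ)/S_Exp − 1`, flow proxy its
circular phase derivative) is correlated with a healthy reference loop
averaged over voxels in the 75th–95th RVent percentile band; loop
correlations below 90% define the **FVL VDP**.

Heterogeneity of the trimmed RVent histogram (values above the 99th
percentile excluded) is summarized by

* **IQD** = interquartile range / mean,
* **IHI** = Σ|RVent − median(RVent)| / Σ RVent,
* skewness and (non-excess) kurtosis.

Cohort statistics follow the clinical-study pattern: Shapiro–Wilk-routed
Student-t/Mann–Whitney group comparisons, paired-t/Wilcoxon pre/post tests,
Spearman correlations against lung function with Hochberg step-up
adjustment, and a binary (gas-trapping-style) stratification.

## Worked example

```python
from prefulvent import PhantomParams, analyze_series, synthesize_series

params = PhantomParams(defect_fraction=0.15, lag_fraction=0.10, seed=11)
series, truth = synthesize_series(params)      # 128x128x250 @ 135 ms/frame
result = analyze_series(series, truth.lung_mask)
```

Running `python examples/analyze_single_subject.py` (this exact analysis)
prints:

```
respiratory frequency: 0.2500 Hz (programmed 0.2500 Hz)
cosine fit quality (R^2): 1.000
key phase bins — end-expiration: 14, mid: 3, end-inspiration: 7
RVent threshold (0.4 x P90): 0.0979
VDP_RVent: 25.0%  (defect programmed at 15%)
VDP_FVL:   25.0%  (defects + phase-lagged regions both fail the 90% loop correlation)
IQD: 1.321   IHI: 0.404
```

The 15% non-ventilated patch and the 10% quarter-cycle-lagged patch are
both recovered: a π/2 lag leaves a voxel near its mid-cycle level at the
global end-inspiratory/end-expiratory states, so its apparent RVent is ~0
and its loop decorrelates from the reference — hence both VDPs read 25%.
The other scripts in `examples/` walk through phantom generation,
heterogeneity metrics, and a full simulated pre/post-bronchodilator cohort
with its statistical report.

A thin CLI wraps the same pipeline for shell use:

```bash
prefulvent simulate --out phantoms --seed 1 --n-healthy 2 --n-disease 2
prefulvent analyze --series phantoms/S000_pre_series.nii.gz \
                   --mask phantoms/S000_pre_lung_mask.nii.gz --out out
prefulvent cohort --metrics metrics.csv --out stats
```

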