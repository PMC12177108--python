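"""Histogram heterogeneity metrics on ventilation maps.

Compares a homogeneous and a heterogeneous lung: IQD (interquartile range
over mean) and IHI (summed absolute deviation from the median over the
total) both grow with the spread of regional ventilation, while remaining
invariant to the overall ventilation level.
"""

import numpy as np

from prefulvent import compute_heterogeneity, pooled_histogram

rng = np.random.default_rng(3)

homogeneous = rng.normal(0.22, 0.01, size=2000).clip(min=1e-3)
heterogeneous = np.concatenate(
    [rng.normal(0.22, 0.06, size=1600), rng.normal(0.02, 0.005, size=400)]
).clip(min=1e-3)

for name, sample in [("homogeneous", homogeneous), ("heterogeneous", heterogeneous)]:
    m = compute_heterogeneity(sample)
    print(f"{name:>14}: IQD={m.iqd:.3f}  IHI={m.ihi:.3f}  "
          f"skew={m.skewness:+.2f}  kurt={m.kurtosis:.2f}  "
          f"(n={m.n_used} after trimming above P99={m.trim_threshold:.3f})")

scaled = compute_heterogeneity(heterogeneous * 10)
print(f"x10 rescaled heterogeneous: IQD={scaled.iqd:.3f} (unchanged — scale-free)")

pooled = pooled_histogram({"homog": [homogeneous], "heterog": [heterogeneous]}, n_bins=30)
for group, sub in pooled.groupby("group"):
    width = sub["bin_left"].iloc[1] - sub["bin_left"].iloc[0]
    print(f"pooled density of {group!r} integrates to "
          f"{(sub['density'].sum() * width):.6f} over the median-rescaled grid")
# The heterogeneous lung roughly doubles both IQD and IHI — the same
# qualitative contrast seen between diseased and healthy lungs.
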