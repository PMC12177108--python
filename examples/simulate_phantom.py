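"""Generate a synthetic free-breathing lung-MRI series with a programmed
ventilation defect and inspect its ground truth.

The phantom's parenchymal signal falls on inspiration and rises on
expiration; a 20% patch of the lung is given near-zero ventilation
amplitude (a 'defect'), which the downstream analysis should recover as a
~20% ventilation defect percentage.
"""

import numpy as np

from prefulvent import PhantomParams, synthesize_series

params = PhantomParams(defect_fraction=0.2, noise_sd=0.02, seed=7)
series, truth = synthesize_series(params)

n_lung = truth.lung_mask.sum()
print(f"series shape (ny, nx, frames): {series.signal.shape}")
print(f"frame interval: {series.frame_interval * 1000:.0f} ms "
      f"({series.n_frames * series.frame_interval:.1f} s total)")
print(f"lung area: {n_lung} voxels "
      f"({100 * n_lung / series.signal[:, :, 0].size:.1f}% of the grid)")
print(f"programmed defect area: {truth.defect_mask.sum()} voxels "
      f"({100 * truth.defect_mask.sum() / n_lung:.1f}% of the lung)")

m = series.mean_signal(truth.lung_mask)
print(f"mean lung signal swings {m.min():.1f}-{m.max():.1f} a.u. over the "
      "respiratory cycle (minimum at end-inspiration)")
print(f"respiratory frequency programmed: {truth.respiratory_frequency:.3f} Hz")
# The defect area fraction is the ground truth the RVent VDP should recover.
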