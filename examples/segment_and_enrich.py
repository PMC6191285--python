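"""Segment granules in a synthetic field and measure their fold enrichment.

Renders 23 granules at a true 21-fold intensity over the intergranular
space (with PSF blur and Poisson noise), segments them, and estimates the
enrichment from the brightest pixel of each granule against 20 reference
ROIs placed in granule-free background.
"""

import numpy as np

from granulekit.morphometry import (
    disk_roi, fold_enrichment, records_to_mask, segment_granules)
from granulekit.simulate import (
    SimulationConfig, place_granules, simulate_granule_image)

cfg = SimulationConfig(seed=42)  # 50 nm px, PSF sigma 1.6 px, Poisson noise
truths = place_granules(cfg, 23, radius_nm=211.0, enrichment=21.0,
                        shape=(512, 512))
stack, truths = simulate_granule_image(cfg, truths, background_level=200.0)

records = segment_granules(stack, threshold_k=3.0, min_area_nm2=5e4)
print(f"segmented {len(records)} granules (truth: {len(truths)})")
diams = [r.equivalent_diameter_nm for r in records]
print(f"equivalent diameter: {np.mean(diams):.0f} +- {np.std(diams):.0f} nm "
      "(d = 2 sqrt(A) convention)")

occupied = records_to_mask(records, stack.shape_yx)
rng = np.random.default_rng(1)
rois = []
while len(rois) < 20:
    cy, cx = rng.uniform(8, 503, 2)
    roi = disk_roi(stack.shape_yx, (cy, cx), 6)
    if not (roi & occupied).any():
        rois.append(roi)

res = fold_enrichment(stack, records, rois, reference_kind="intergranular",
                      granule_measure="peak")
print(f"fold enrichment over intergranular space: {res.fold_enrichment:.1f}x "
      "(truth 21.0x)")
print()
print("The peak estimator reads each granule's interior concentration; ROI")
print("means would be diluted by the PSF at this granule size (~420 nm).")
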