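"""Quantify compartment exchange by fluorescence loss in photobleaching.

Continuously bleaches region A of a four-region chain (A-B-C-D) whose
neighbors exchange mobile protein, records percent fluorescence remaining
in every region, and corrects the depletion with a control bleach target
outside the specimen that reports unintended acquisition bleaching.
"""

import numpy as np

from granulekit.photokinetics import flip_analysis
from granulekit.simulate import (
    KineticTruth, SimulationConfig, chain_coupling, simulate_flip)

cfg = SimulationConfig(seed=0, poisson=False, gaussian_sigma=0.0)
truth = KineticTruth(mobile_fraction=0.45, k_bleach_per_s=0.6, k_img_per_s=0.001,
                     coupling_per_s=chain_coupling(4, 0.04), n_pre=1)
regions = simulate_flip(truth, cfg, n_regions=4, bleach_region=0,
                        duration_s=240.0)

control_truth = KineticTruth(mobile_fraction=0.45, k_bleach_per_s=0.0,
                             k_img_per_s=0.001,
                             coupling_per_s=np.zeros((1, 1)), n_pre=1)
control = simulate_flip(control_truth, cfg, 1, 0, 240.0)

res = flip_analysis(regions, control)
print(f"control depletion (unintended bleaching): {res.control_depletion:.1f} %")
for label, dep, corr in zip(res.labels, res.depletion,
                            res.corrected_redistribution):
    print(f"{label}: {dep:5.1f} % lost, corrected redistribution {corr:5.1f} %")
print()
print("Loss in the unbleached regions B-D beyond the control reflects their")
print("mobile pool draining into the bleached region A; the immobile 55%")
print("cannot exchange and caps the achievable depletion.")
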