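"""Follow photoconverted protein as it redistributes among granules.

Converts one granule of a coupled pair (green-to-red switching) and tracks
the converted species: retention in the targeted granule and appearance in
its neighbor.  An isolated control granule shows that without coupling the
converted signal stays put.
"""

from granulekit.photokinetics import photoconversion_analysis
from granulekit.simulate import (
    KineticTruth, SimulationConfig, chain_coupling, simulate_photoconversion)

cfg = SimulationConfig(seed=0, poisson=False, gaussian_sigma=0.0)

coupled = KineticTruth(mobile_fraction=0.9, k_img_per_s=0.0,
                       coupling_per_s=chain_coupling(2, 0.03))
conv, _ = simulate_photoconversion(coupled, cfg, 2, converted_regions=[0],
                                   duration_s=234.0)
res = photoconversion_analysis(conv, targeted=[0])
print("coupled pair, converted granule 0:")
print(f"  retention at 234 s: {res.retention[0][-1]:.1f} %")
print(f"  appearance in granule 1: {res.appearance[1][-1]:.1f} %")

import numpy as np
isolated = KineticTruth(mobile_fraction=0.9, k_img_per_s=0.0,
                        coupling_per_s=np.zeros((1, 1)))
conv_iso, _ = simulate_photoconversion(isolated, cfg, 1, [0], 234.0)
res_iso = photoconversion_analysis(conv_iso, targeted=[0])
print(f"isolated granule retention at 234 s: {res_iso.retention[0][-1]:.1f} %")
print()
print("Signal leaving the targeted granule and appearing in its neighbor is")
print("direct evidence of dynamic exchange; an isolated granule keeps 100%.")
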