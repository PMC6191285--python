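"""Fit the mobile fraction and recovery half-time of a bleached granule.

Simulates ten FRAP traces of a condensed granule protein (43.6% of molecules
exchanging with a 10.5 s half-time), normalizes them full-scale, averages,
and fits the single-term exponential f(t) = a(1 - exp(-bt)).
"""

from granulekit.photokinetics import LN2, fit_frap_session
from granulekit.simulate import KineticTruth, SimulationConfig, simulate_frap_trace

truth = KineticTruth(mobile_fraction=0.436, rate_per_s=LN2 / 10.5,
                     bleach_depth=0.8, n_pre=5)
traces = [
    simulate_frap_trace(
        truth, SimulationConfig(seed=i, poisson=False, gaussian_sigma=0.02),
        duration_s=240.0)
    for i in range(10)
]
fit = fit_frap_session(traces, mode="full_scale")

print(f"mobile fraction a = {fit.mobile_fraction:.1f} % "
      f"(fit SE {fit.se_mobile_fraction:.2f})")
print(f"rate b            = {fit.rate_per_s:.4f} /s")
print(f"half-time t1/2    = {fit.half_time_s:.1f} s   (ln 2 / b)")
print(f"r^2               = {fit.r_squared:.4f} over {fit.n_curves_averaged} curves")
print()
print("The mobile fraction is the plateau of the normalized recovery curve:")
print("the percentage of fluorophore that exchanges with the surroundings.")
print("The immobile remainder (here ~56%) marks a phase-transitioned granule.")
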