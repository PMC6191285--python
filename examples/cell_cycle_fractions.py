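"""Deconvolve a DNA-content histogram into cell-cycle fractions.

Simulates 20,000 cells with 50% G1 / 20% S / 30% G2-M, fits the
Dean-Jett-Fox-style mixture (G2 mean fixed at twice the G1 mean, S phase as
ten Gaussian sub-components), and reports the recovered fractions.
"""

from granulekit.population import fit_cell_cycle
from granulekit.simulate import simulate_dna_histogram

truth = (0.5, 0.2, 0.3)
centers, counts = simulate_dna_histogram(truth, g1_mean=100.0, cv=0.05,
                                         n_cells=20_000, seed=11)
fit = fit_cell_cycle(centers, counts)

for name, got, want in zip(("G1", "S", "G2/M"), fit.fractions, truth):
    print(f"{name:4s}: {got:5.1f} %  (truth {100 * want:.0f} %)")
print(f"G1 mean {fit.g1_mean:.1f}, G2 mean {fit.g2_mean:.1f} "
      f"(= 2x G1 by the ploidy constraint), CV {fit.cv:.3f}")
print()
print("The fractions are the fitted component masses; overlap between the S")
print("tails and the G1/G2 peaks is resolved by the shared-CV mixture model.")
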