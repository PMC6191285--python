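"""Population-level summaries and the cell-cycle histogram fit.

Covers the summary statistics reported across granules, cells and embryos
(mean +- SD/SEM, percent change, unpaired t-tests, one-way ANOVA) and a
Dean-Jett-Fox-style least-squares deconvolution of DNA-content histograms
into G1 / S / G2-M fractions, with the G2/M mean constrained to twice the G1
mean (the ploidy constraint) and a CV shared between the two cycling peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import FitConvergenceError, ParameterError


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    sem: float
    label: str = ""


@dataclass
class CellCycleFit:
    """G1/S/G2M fractions (percent, summing to 100) from a DNA histogram."""

    fraction_g1: float
    fraction_s: float
    fraction_g2m: float
    g1_mean: float
    g2_mean: float  # always exactly 2 * g1_mean
    cv: float
    residual_norm: float

    @property
    def fractions(self) -> tuple:
        return (self.fraction_g1, self.fraction_s, self.fraction_g2m)


def summarize(values, label: str = "") -> GroupSummary:
    """Sample mean, SD (n-1 denominator) and SEM of one group."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("cannot summarize an empty group")
    n = values.size
    mean = float(values.mean())
    if n == 1:
        warnings.warn("single observation: SD reported as 0", stacklevel=2)
        return GroupSummary(1, mean, 0.0, 0.0, label)
    sd = float(values.std(ddof=1))
    return GroupSummary(n, mean, sd, sd / np.sqrt(n), label)


def percent_change(control_mean: float, test_mean: float) -> float:
    """Percent decrease from control to test: 100 (control - test) / control."""
    if control_mean == 0:
        raise ParameterError("control mean is zero: percent change undefined")
    return 100.0 * (control_mean - test_mean) / control_mean


def two_sample_test(group_a, group_b, kind: str = "welch") -> tuple:
    """Two-tailed unpaired t-test; returns (t statistic, p value).

    ``welch`` (default) does not assume equal variances; ``student`` is the
    classical equal-variance test.  Two degenerate groups (zero variance,
    equal means) return (0, 1) by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    if kind not in ("welch", "student"):
        raise ParameterError(f"unknown test kind {kind!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    res = stats.ttest_ind(a, b, equal_var=(kind == "student"))
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups) -> tuple:
    """Classical one-way ANOVA; returns (F statistic, p value)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ParameterError("ANOVA needs >= 2 groups")
    for g in groups:
        if g.size < 2:
            raise ParameterError("every group needs n >= 2")
    if all(g.std(ddof=1) == 0 for g in groups):
        raise ParameterError("all groups are degenerate (zero variance)")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# DNA-content deconvolution
# ---------------------------------------------------------------------------
N_S_COMPONENTS = 10


def _djf_profile(x, g1_mean, cv, mass_g1, mass_s, mass_g2, binwidth):
    def gauss(mu):
        sd = cv * mu
        return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))

    out = mass_g1 * gauss(g1_mean) + mass_g2 * gauss(2.0 * g1_mean)
    for i in range(N_S_COMPONENTS):
        mu = g1_mean * (1.0 + (i + 0.5) / N_S_COMPONENTS)
        out = out + (mass_s / N_S_COMPONENTS) * gauss(mu)
    return out * binwidth


def fit_cell_cycle(bin_centers, counts) -> CellCycleFit:
    """Deconvolve a DNA-content histogram into G1, S and G2/M fractions.

    Least-squares mixture fit of a G1 Gaussian, a G2/M Gaussian fixed at
    twice the G1 mean, and an S-phase plateau discretized as 10 evenly spaced
    Gaussian sub-components between the two, all sharing one relative CV.
    Fractions are the fitted component masses normalized to 100%.
    """
    x = np.asarray(bin_centers, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.size != y.size:
        raise ParameterError("bin_centers and counts must match")
    if x.size < 50:
        raise ParameterError("need >= 50 bins spanning both modes")
    total = float(y.sum())
    if total <= 0:
        raise ParameterError("histogram is empty")
    binwidth = float(np.median(np.diff(x)))

    g1_guess = float(x[np.argmax(y)])
    p0 = np.array([g1_guess, 0.05, 0.5 * total, 0.2 * total, 0.3 * total])
    lo = np.array([0.25 * g1_guess, 0.005, 0.0, 0.0, 0.0])
    hi = np.array([2.0 * g1_guess, 0.5, 2 * total, 2 * total, 2 * total])

    def resid(p):
        return _djf_profile(x, *p, binwidth) - y

    sol = optimize.least_squares(resid, p0, bounds=(lo, hi), max_nfev=20000)
    if not sol.success:
        raise FitConvergenceError("cell-cycle mixture fit did not converge",
                                  p0=tuple(p0),
                                  residual_norm=float(np.linalg.norm(sol.fun)))
    g1_mean, cv, m1, ms, m2 = sol.x
    mass = m1 + ms + m2
    if mass <= 0:
        raise FitConvergenceError("cell-cycle fit collapsed to zero mass")
    f1, fs, f2 = 100.0 * m1 / mass, 100.0 * ms / mass, 100.0 * m2 / mass
    if f2 < 0.1:
        warnings.warn("G2/M mass below 0.1%: histogram looks unimodal", stacklevel=2)
    return CellCycleFit(
        fraction_g1=float(f1),
        fraction_s=float(fs),
        fraction_g2m=float(f2),
        g1_mean=float(g1_mean),
        g2_mean=float(2.0 * g1_mean),
        cv=float(cv),
        residual_norm=float(np.linalg.norm(sol.fun)),
    )
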