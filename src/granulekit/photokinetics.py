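"""FRAP, FLIP and photoconversion quantification.

The central model is single-term exponential recovery,

    f(t) = a * (1 - exp(-b * t)),

where ``a`` is the mobile fraction (the plateau of the normalized recovery
curve, i.e. the proportion of fluorophore that exchanges with the
surroundings) and ``b`` the recovery rate constant, related to the half-time
of recovery by t1/2 = ln(2) / b.  FRAP traces are background-subtracted,
reference-normalized ("double" normalization) and optionally rescaled so that
the first post-bleach value is exactly 0 and the pre-bleach mean exactly 1
("full-scale" normalization), which removes differences in bleach depth
between experiments.  Curves are averaged across ROIs before fitting.

FLIP traces are expressed as percent fluorescence remaining relative to the
first frame, with depletion corrected by the apparent loss measured while
bleaching a control target outside the specimen (unintended acquisition
bleaching); no reference-ROI normalization is applied.  Photoconverted-species
traces are summarized as retention of the targeted granules and appearance in
non-targeted granules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    FitConvergenceError,
    NormalizationError,
    NoRecoveryError,
    ParameterError,
)

log = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class RecoveryTrace:
    """Time-resolved intensities of one photobleaching/photoconversion ROI.

    ``time_s`` must be a strictly increasing, uniform grid.  ``n_pre`` counts
    the frames acquired before the perturbation (5 in a typical FRAP session,
    establishing pre-bleach fluorescence).
    """

    time_s: np.ndarray
    roi_intensity: np.ndarray
    reference_intensity: np.ndarray | None = None
    background_intensity: np.ndarray | None = None
    n_pre: int = 5
    label: str = ""

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.roi_intensity = np.asarray(self.roi_intensity, dtype=float)
        if self.reference_intensity is not None:
            self.reference_intensity = np.asarray(self.reference_intensity, dtype=float)
        if self.background_intensity is not None:
            self.background_intensity = np.asarray(self.background_intensity, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.size < 2:
            raise ParameterError("time_s must be a 1-D grid with >= 2 samples")
        if self.roi_intensity.shape != self.time_s.shape:
            raise ParameterError("roi_intensity must match the time grid")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ParameterError("time_s must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1.0):
            raise ParameterError("time_s must be uniform to 1e-9 relative tolerance")
        if self.n_pre < 0:
            raise ParameterError("n_pre must be >= 0")

    @property
    def frame_interval_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])


@dataclass
class NormalizedCurve:
    """A normalized recovery curve on a uniform time grid."""

    time_s: np.ndarray
    values: np.ndarray
    n_pre: int
    bleach_index: int
    mode: str = "full_scale"
    label: str = ""


@dataclass
class FitResult:
    """Parameters of a single-exponential recovery fit.

    ``mobile_fraction`` is in percent (0-100 scale); ``half_time_s`` is the
    derived quantity ln(2)/b, never fitted independently.  Standard errors are
    taken from the fit covariance and labeled as such.
    """

    mobile_fraction: float
    rate_per_s: float
    half_time_s: float
    se_mobile_fraction: float
    se_rate_per_s: float
    r_squared: float
    n_curves_averaged: int = 1

    def __post_init__(self):
        if not np.isclose(self.half_time_s * self.rate_per_s, LN2, rtol=1e-12):
            raise ParameterError("half_time_s must equal ln(2)/rate")
        if self.mobile_fraction > 110:
            warnings.warn(
                f"mobile fraction {self.mobile_fraction:.1f}% exceeds 110%: over-recovery",
                stacklevel=2,
            )

    def ci95_mobile_fraction(self) -> tuple:
        """Normal-approximation 95% confidence interval for the mobile fraction."""
        h = 1.959963984540054 * self.se_mobile_fraction
        return (self.mobile_fraction - h, self.mobile_fraction + h)


@dataclass
class FlipResult:
    """Percent-remaining summary of one FLIP session."""

    time_s: np.ndarray
    percent_remaining: np.ndarray  # (n_regions, n_frames), 100 at t = 0
    labels: list
    depletion: np.ndarray  # 100 - final percent remaining, per region
    control_depletion: float
    corrected_redistribution: np.ndarray  # depletion - control, floored at 0
    control_applied: bool = True


@dataclass
class PhotoconversionResult:
    """Retention/appearance summary of a photoconversion session (percent)."""

    time_s: np.ndarray
    retention: dict = field(default_factory=dict)  # region index -> % curve
    appearance: dict = field(default_factory=dict)  # region index -> % curve


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------
def find_bleach_index(values: np.ndarray, n_pre: int) -> int:
    """Locate the bleach frame as the minimum within [n_pre, n_pre + 2].

    A single-pulse bleach protocol guarantees the global minimum immediately
    after the pulse, so only a short window past the pre-bleach block is
    searched.
    """
    lo = n_pre
    hi = min(n_pre + 3, len(values))
    if lo >= len(values):
        raise ParameterError("trace has no post-bleach frames")
    return lo + int(np.argmin(values[lo:hi]))


def normalize_frap(trace: RecoveryTrace, mode: str = "full_scale") -> NormalizedCurve:
    """Normalize a FRAP trace.

    ``double``: background-subtract ROI and reference, divide ROI by reference
    (cancelling acquisition bleaching) and scale so the pre-bleach mean is 1.
    ``full_scale``: additionally map the first post-bleach value to exactly 0,

        F_fs(t) = (F_n(t) - F_n(t_bleach)) / (1 - F_n(t_bleach)),

    so curves with different bleach depths are directly comparable and the
    fitted plateau is the mobile fraction.
    """
    if mode not in ("double", "full_scale"):
        raise ParameterError(f"unknown normalization mode {mode!r}")
    if trace.n_pre < 1:
        raise ParameterError("FRAP normalization requires >= 1 pre-bleach frame")
    if trace.n_pre >= len(trace.time_s):
        raise ParameterError("trace has no post-bleach frames")
    if trace.reference_intensity is None:
        raise ParameterError(f"{mode} normalization requires a reference ROI")

    bg = 0.0
    if trace.background_intensity is not None:
        bg = float(np.mean(trace.background_intensity))
    roi = trace.roi_intensity - bg
    ref = trace.reference_intensity - bg
    if np.any(ref <= 0):
        raise NormalizationError("background-subtracted reference is non-positive")

    ratio = roi / ref
    pre_mean = float(np.mean(ratio[: trace.n_pre]))
    if pre_mean <= 0:
        raise NormalizationError("pre-bleach mean is non-positive")
    fn = ratio / pre_mean
    bleach_index = find_bleach_index(fn, trace.n_pre)

    if mode == "double":
        return NormalizedCurve(trace.time_s, fn, trace.n_pre, bleach_index, mode, trace.label)

    f_bleach = fn[bleach_index]
    if f_bleach >= 1.0 - 1e-12:
        raise NormalizationError(
            "no bleach depth: normalized value at the bleach frame is >= 1"
        )
    full = (fn - f_bleach) / (1.0 - f_bleach)
    return NormalizedCurve(trace.time_s, full, trace.n_pre, bleach_index, mode, trace.label)


def aggregate_curves(curves) -> tuple:
    """Pointwise mean and SEM of normalized curves sharing one time grid.

    Returns ``(mean_curve, sem)`` where ``mean_curve`` is a
    :class:`NormalizedCurve` and ``sem`` the pointwise standard error of the
    mean (sample SD / sqrt(n); zero for n = 1).  Grids are never resampled:
    mismatched grids raise.
    """
    curves = list(curves)
    if not curves:
        raise ParameterError("no curves to aggregate")
    t0 = curves[0].time_s
    for c in curves[1:]:
        if c.time_s.shape != t0.shape or np.max(np.abs(c.time_s - t0)) > 1e-9:
            raise ParameterError("curves do not share a common time grid")
        if c.n_pre != curves[0].n_pre:
            raise ParameterError("curves disagree on the pre-bleach block")
    # under a single-pulse protocol the earliest located minimum is the pulse
    # frame; later indices are noise jitter within the search window
    bleach_index = min(c.bleach_index for c in curves)
    stack = np.vstack([c.values for c in curves])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    out = NormalizedCurve(
        t0, mean, curves[0].n_pre, bleach_index, curves[0].mode,
        label=f"mean of {n} curves",
    )
    return out, sem


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------
def _recovery_model(t, a, b):
    return a * (1.0 - np.exp(-b * t))


def fit_recovery(curve: NormalizedCurve, n_curves_averaged: int | None = None) -> FitResult:
    """Fit f(t) = a(1 - exp(-bt)) to the post-bleach part of a curve.

    Times are re-zeroed at the bleach frame.  The fit runs on the 0-1 scale;
    the mobile fraction is reported in percent.  Initial guesses: a0 = mean of
    the last 10% of the curve, b0 = ln2 over the first time the curve exceeds
    a0/2 (derivative-free and robust).
    """
    i0 = curve.bleach_index
    tau = curve.time_s[i0:] - curve.time_s[i0]
    y = curve.values[i0:]
    if len(y) < 5:
        raise ParameterError("need >= 5 post-bleach points to fit")
    if abs(y[0]) > 0.1:
        raise ParameterError(
            "curve does not start near 0; apply full-scale normalization first"
        )

    tail = y[max(len(y) - max(len(y) // 10, 2), 1):]
    a0 = float(np.mean(tail))
    if a0 <= 0:
        raise NoRecoveryError("curve shows no recovery (non-positive plateau estimate)")
    above = np.nonzero(y > a0 / 2)[0]
    above = above[above > 0]
    t_half0 = tau[above[0]] if above.size else tau[-1] / 4
    b0 = LN2 / max(t_half0, tau[1])
    p0 = (min(a0, 1.4), b0)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _recovery_model, tau, y, p0=p0,
                bounds=([0.0, 1e-9], [1.5, np.inf]), maxfev=10000,
            )
    except RuntimeError as exc:
        resid = float(np.linalg.norm(y - _recovery_model(tau, *p0)))
        raise FitConvergenceError(
            f"recovery fit did not converge: {exc}", p0=p0, residual_norm=resid
        ) from exc

    a, b = popt
    if b <= 1e-8 or a <= 1e-6:
        raise NoRecoveryError("fitted rate or amplitude is non-positive: no recovery")
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    ss_res = float(np.sum((y - _recovery_model(tau, a, b)) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(
        mobile_fraction=100.0 * a,
        rate_per_s=float(b),
        half_time_s=LN2 / float(b),
        se_mobile_fraction=100.0 * float(perr[0]),
        se_rate_per_s=float(perr[1]),
        r_squared=r2,
        n_curves_averaged=n_curves_averaged or getattr(curve, "n_curves", 1) or 1,
    )


def fit_frap_session(traces, mode: str = "full_scale") -> FitResult:
    """Normalize, average and fit a set of FRAP traces (the default pipeline)."""
    curves = [normalize_frap(tr, mode=mode) for tr in traces]
    mean_curve, _ = aggregate_curves(curves)
    return fit_recovery(mean_curve, n_curves_averaged=len(curves))


# ---------------------------------------------------------------------------
# FLIP
# ---------------------------------------------------------------------------
def percent_remaining(trace: RecoveryTrace, anchor: str = "first") -> np.ndarray:
    """Express a trace as percent of its initial fluorescence.

    ``anchor='first'`` uses the raw time-0 value (default); ``'pre_mean'``
    uses the mean of the ``n_pre`` first frames.
    """
    if anchor == "first":
        f0 = float(trace.roi_intensity[0])
    elif anchor == "pre_mean":
        f0 = float(np.mean(trace.roi_intensity[: max(trace.n_pre, 1)]))
    else:
        raise ParameterError(f"unknown anchor {anchor!r}")
    if f0 <= 0:
        raise ParameterError("zero or negative initial intensity")
    return 100.0 * trace.roi_intensity / f0


def flip_analysis(region_traces, control_traces=None, anchor: str = "first") -> FlipResult:
    """Quantify fluorescence loss in photobleaching across regions.

    Each region trace is converted to percent remaining relative to its own
    initial value (no reference-ROI normalization).  Endpoint depletion is
    100 minus the final percent remaining.  When control traces from a bleach
    target outside the specimen are supplied, their mean depletion estimates
    unintended acquisition bleaching and is subtracted from every region's
    depletion; corrected values are floored at 0 (depletion below control is
    noise by construction; negative corrections are logged).
    """
    region_traces = list(region_traces)
    if not region_traces:
        raise ParameterError("no region traces")
    t0 = region_traces[0].time_s
    for tr in region_traces[1:]:
        if tr.time_s.shape != t0.shape or np.max(np.abs(tr.time_s - t0)) > 1e-9:
            raise ParameterError("region traces do not share a common time grid")

    pct = np.vstack([percent_remaining(tr, anchor) for tr in region_traces])
    depletion = 100.0 - pct[:, -1]

    control_applied = control_traces is not None
    if control_applied:
        ctrl = [percent_remaining(tr, anchor) for tr in control_traces]
        control_depletion = float(np.mean([100.0 - c[-1] for c in ctrl]))
    else:
        warnings.warn("no control traces: unintended-bleaching correction skipped",
                      stacklevel=2)
        control_depletion = 0.0

    corrected = depletion - control_depletion
    if np.any(corrected < 0):
        log.info("negative corrected redistribution floored at 0: %s",
                 np.round(corrected, 3))
    corrected = np.clip(corrected, 0.0, None)
    labels = [tr.label or f"region {i}" for i, tr in enumerate(region_traces)]
    return FlipResult(t0, pct, labels, depletion, control_depletion, corrected,
                      control_applied)


# ---------------------------------------------------------------------------
# photoconversion
# ---------------------------------------------------------------------------
def photoconversion_analysis(converted_traces, targeted) -> PhotoconversionResult:
    """Summarize converted-channel traces after targeted photoconversion.

    Targeted granules report *retention*: converted intensity as percent of
    their own first post-conversion value.  Non-targeted granules report
    *appearance*: converted intensity as percent of the mean initial intensity
    of the targeted granules (signal can only arrive by exchange).
    """
    converted_traces = list(converted_traces)
    targeted = sorted(set(targeted))
    if not targeted:
        raise ParameterError("targeted region set is empty")
    n = len(converted_traces)
    if any(i < 0 or i >= n for i in targeted):
        raise ParameterError("targeted index out of range")

    initials = [float(converted_traces[i].roi_intensity[0]) for i in targeted]
    if all(v <= 0 for v in initials):
        raise ParameterError("zero post-conversion intensity in all targeted regions")
    mean_initial = float(np.mean(initials))

    result = PhotoconversionResult(time_s=converted_traces[0].time_s)
    for i, tr in enumerate(converted_traces):
        if i in targeted:
            f0 = float(tr.roi_intensity[0])
            if f0 <= 0:
                raise ParameterError(f"targeted region {i} has zero initial intensity")
            result.retention[i] = 100.0 * tr.roi_intensity / f0
        else:
            result.appearance[i] = 100.0 * tr.roi_intensity / mean_initial
    return result
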