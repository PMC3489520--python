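"""Per-reaction processing of raw qPCR amplification and melt curves.

A SYBR-green qPCR trace is, per cycle, ``F(c) = baseline + A(c) + noise``
where the product signal ``A`` grows geometrically at the reaction's
amplification efficiency ``E`` (1 < E <= 2 ideally) until reagent depletion
flattens it.  This module recovers, for each well:

* the constant background *baseline* (``strict`` log-linearity search or the
  minimum-fluorescence fallback),
* the *window of linearity*: the cycle range over which log10 of the
  corrected signal is linear in cycle number,
* the per-reaction efficiency ``E = 10**slope`` of the window regression,
* the quantification cycle ``Cq`` at a fixed fluorescence threshold ``Nt``
  (fractional, interpolated from the window regression), and
* the starting concentration ``N0 = Nt / E**Cq``.

Melt-curve peak detection (local maxima of -dF/dT) lives here as well, used
downstream to tell primer-dimer signal in no-template controls apart from
genuine product.

Conventions: cycles are 1-based, windows are inclusive on both ends, and all
logarithms are base 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

ROLES = frozenset({"standard", "unknown", "ntc", "calibrator"})
TARGETS = frozenset({"telomere", "reference"})

MIN_CYCLES = 10


class InvalidParameterError(ValueError):
    """A parameter violates its documented domain."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluorescenceTrace:
    """One well's raw per-cycle readings plus its plate metadata."""

    batch: str
    well: str
    role: str
    target: str
    sample: str
    replicate: int
    expected_ng: float | None
    readings: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InvalidParameterError(f"unknown role {self.role!r}")
        if self.target not in TARGETS:
            raise InvalidParameterError(f"unknown target {self.target!r}")
        readings = np.asarray(self.readings, dtype=float)
        object.__setattr__(self, "readings", readings)
        if readings.ndim != 1 or readings.size < MIN_CYCLES:
            raise InvalidParameterError(
                f"trace {self.batch}:{self.well} needs >= {MIN_CYCLES} cycles"
            )
        if not np.all(np.isfinite(readings)):
            raise InvalidParameterError(
                f"trace {self.batch}:{self.well} has non-finite readings"
            )
        if self.role == "standard" and (
            self.expected_ng is None or not self.expected_ng > 0
        ):
            raise InvalidParameterError(
                f"standard well {self.batch}:{self.well} lacks expected_ng"
            )

    @property
    def cycles(self) -> int:
        return int(self.readings.size)


@dataclass(frozen=True)
class MeltCurve:
    """Post-amplification dissociation readings for one well."""

    batch: str
    well: str
    temperatures: np.ndarray
    readings: np.ndarray
    peaks: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.readings, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "readings", f)
        if t.size != f.size:
            raise InvalidParameterError("temperature/reading length mismatch")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidParameterError("temperatures must be strictly ascending")


@dataclass
class ProcessedTrace:
    """A trace after baseline correction.

    ``corrected`` holds ``readings - baseline`` with non-positive values
    masked as NaN (they are excluded from any log fit, never clamped).
    ``noise`` is a robust estimate of the per-reading noise SD taken from the
    early cycles; a small multiple of it serves as the usable-signal floor
    downstream.
    """

    trace: FluorescenceTrace
    baseline: float
    corrected: np.ndarray
    noise: float
    usable: bool
    mode: str


@dataclass
class WindowFit:
    """Log-linear regression of one trace over its window of linearity."""

    start: int
    end: int
    slope: float
    intercept: float
    r2: float
    n_points: int
    individual: bool = False

    @property
    def efficiency(self) -> float:
        return float(10.0 ** self.slope)


@dataclass
class AmplificationFit:
    """Full per-reaction result: baseline, window, E, Cq and N0."""

    baseline: float
    window: tuple[int, int] | None
    efficiency: float
    fit_r2: float
    cq: float
    n0: float
    threshold_used: float
    usable: bool
    individual_window: bool = False
    slope: float = math.nan
    intercept: float = math.nan


# ---------------------------------------------------------------------------
# small numeric helpers
# ---------------------------------------------------------------------------


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares of y on x; returns (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x.mean()
    ym = y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise InvalidParameterError("zero variance in x")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    if ss_tot > 0.0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    return slope, float(intercept), float(r2)


def _noise_estimate(readings: np.ndarray) -> float:
    """Robust noise SD from first differences of the early (pre-signal) cycles.

    The MAD of so few differences occasionally collapses by chance (half the
    deviations landing near zero), which would wreck every downstream floor
    and onset threshold, so the estimate is backstopped by a 70th-percentile
    scale from a slightly longer head; both are consistent for Gaussian noise
    and the later head cycles at most double the estimate when amplification
    starts early, which is the benign direction.
    """
    head = np.asarray(readings[:14], dtype=float)
    d = np.diff(head)
    if d.size == 0:
        return 0.0
    dev = np.abs(d - np.median(d))
    mad = float(np.median(dev[: max(1, dev.size - 4)])) * 1.4826 / math.sqrt(2.0)
    p70 = float(np.percentile(dev, 70.0)) / (1.0364 * math.sqrt(2.0))
    return max(mad, p70)


def _mask_nonpositive(values: np.ndarray) -> np.ndarray:
    out = np.asarray(values, dtype=float).copy()
    out[~(out > 0.0)] = np.nan
    return out


# ---------------------------------------------------------------------------
# baseline correction
# ---------------------------------------------------------------------------

_REGION_LEN = 8  # points used to score a candidate baseline
_FLOOR_MULT = 2.0  # usable-signal floor, in units of the noise SD


def _cap_fraction(g: np.ndarray) -> float:
    """Upper usable-signal fraction of the corrected maximum.

    Once a trace has visibly flattened, cycles above half of the maximum are
    already slowed by reagent depletion and would bend any log-linear fit;
    for still-growing traces the cap stays at the 90% plateau guard.
    """
    finite = g[np.isfinite(g)]
    if finite.size == 0:
        return 0.9
    gmax = float(finite.max())
    early = np.nan_to_num(g[: max(1, g.size - 4)], nan=-np.inf)
    late_growth = gmax - float(np.max(early))
    return _PLATEAU_CAP if late_growth < 0.05 * gmax else 0.9


def _candidate_region(readings: np.ndarray, noise: float) -> np.ndarray | None:
    """Fixed candidate exponential region for the strict baseline search.

    Determined once from a rough (median early-cycle) correction so that the
    scored point set does not change with the candidate constant — otherwise
    the search can game R^2 by masking awkward cycles in or out.  The region
    is the first ``_REGION_LEN`` cycles clearly above the noise (3 SD, to keep
    pre-onset noise excursions out) and below the depletion cap: the low end
    of the growth phase is where a baseline error bends the log curve and is
    therefore where the search has its discriminating power.
    """
    b_rough = float(np.median(readings[:8]))
    g = readings - b_rough
    gmax = float(g.max())
    if not gmax > 0:
        return None
    cap = _cap_fraction(g) * gmax
    lo = max(3.0 * noise, 1e-12)
    sel = np.flatnonzero((g > lo) & (g <= cap))
    if sel.size < 4:
        return None
    return sel[:_REGION_LEN]


def _baseline_score(
    readings: np.ndarray, b: float, region: np.ndarray
) -> float:
    """Extrapolation misfit of the log-linear fit for candidate baseline b.

    The line is fitted to the upper half of the fixed candidate region, where
    the signal dwarfs any plausible baseline error, and scored (negatively)
    by its squared misfit to the lower points, where the log curve is
    maximally sensitive to the constant.  Naive whole-region objectives are
    degenerate at both ends of the search: over-subtraction drives a bottom
    point toward log 0 (which *inflates* R^2 through the total variance),
    while under-subtraction compresses the whole log curve (which deflates
    the raw residual SS).  The split objective blows up at both ends.
    """
    g = readings[region] - b
    if np.any(g <= 0):
        return -math.inf
    x = region.astype(float)
    y = np.log10(g)
    half = region.size // 2
    if region.size - half < 2 or half < 1:
        return -math.inf
    slope, intercept, _ = _linfit(x[half:], y[half:])
    if slope <= 0:
        return -math.inf
    resid = y[:half] - (intercept + slope * x[:half])
    return -float((resid**2).sum())


def correct_baseline(trace: FluorescenceTrace, mode: str = "strict") -> ProcessedTrace:
    """Estimate and subtract a constant background from a raw trace.

    ``strict`` searches a grid of candidate constants between 0 and the
    minimum positive early-cycle reading for the one maximizing log10
    linearity of the early exponential region (>= 4 usable points required);
    ``min`` simply subtracts the minimum reading.  A trace without a credible
    amplification signal is returned with ``usable=False`` (baseline = the
    minimum reading), not raised.
    """
    if mode not in ("strict", "min"):
        raise InvalidParameterError(f"unknown baseline mode {mode!r}")
    f = np.asarray(trace.readings, dtype=float)
    noise = _noise_estimate(f)
    floor = _FLOOR_MULT * noise
    span = float(f.max() - f.min())
    flat = span < max(10.0 * noise, 1e-12)

    def _fallback() -> ProcessedTrace:
        b = float(f.min())
        return ProcessedTrace(trace, b, _mask_nonpositive(f - b), noise, False, mode)

    if flat:
        return _fallback()

    if mode == "min":
        b = float(f.min())
        corrected = _mask_nonpositive(f - b)
        usable = int(np.sum(corrected > 0)) >= 4
        return ProcessedTrace(trace, b, corrected, noise, usable, mode)

    # strict: anchor on the flat pre-onset segment (its mean has SD
    # noise/sqrt(k), far tighter than any straightness objective at this
    # signal-to-noise), then refine within +-2 SEM by the straightness score
    b_rough = float(np.median(f[:8]))
    above = f > b_rough + 5.0 * noise
    onset = f.size
    for c in range(f.size - 1):
        if above[c] and above[c + 1]:
            onset = c
            break
    n_base = onset - 3
    region = _candidate_region(f, noise)

    if n_base >= 2:
        b = float(f[:n_base].mean())
        sem = noise / math.sqrt(n_base) if noise > 0 else 0.0
        # search only within the anchor's own uncertainty: any wider and the
        # grid cannot resolve the straightness optimum when noise is tiny
        halfwidth = 2.0 * sem + 1e-9
    else:
        # amplification starts immediately: no flat segment to average;
        # fall back to a full-range straightness search
        if region is None:
            return _fallback()
        upper = float(f[region].min())
        if upper <= 0:
            return _fallback()
        b = upper / 2.0
        halfwidth = upper / 2.0

    if region is not None:
        lo = max(0.0, b - halfwidth)
        hi = b + halfwidth
        grid = np.linspace(lo, hi, 41)
        scores = [_baseline_score(f, g, region) for g in grid]
        best_i = int(np.argmax(scores))
        if math.isfinite(scores[best_i]):
            step = grid[1] - grid[0] if grid.size > 1 else 0.0
            fine = np.linspace(
                max(lo, grid[best_i] - step), min(hi, grid[best_i] + step), 41
            )
            fine_scores = [_baseline_score(f, g, region) for g in fine]
            j = int(np.argmax(fine_scores))
            if math.isfinite(fine_scores[j]):
                b = float(fine[j])
    corrected = _mask_nonpositive(f - b)
    usable = int(np.sum(corrected > max(floor, 0.0))) >= 4
    return ProcessedTrace(trace, b, corrected, noise, usable, mode)


# ---------------------------------------------------------------------------
# window of linearity
# ---------------------------------------------------------------------------


_PLATEAU_CAP = 0.5  # eligible-cycle cap once a trace has visibly plateaued


def _eligible_cycles(pt: ProcessedTrace) -> np.ndarray:
    """1-based cycles usable for log-linear fitting.

    Positive corrected signal above the noise floor and strictly below the
    cycle at which the trace first exceeds 90% of its own corrected maximum.
    For traces that have visibly plateaued the cap tightens to 40% of the
    maximum: growth there is already slowed by reagent depletion and would
    bias the efficiency fit downward.
    """
    g = pt.corrected
    if not np.any(np.isfinite(g)):
        return np.empty(0, dtype=int)
    gmax = float(np.nanmax(g))
    filled = np.nan_to_num(g, nan=-np.inf)
    above = np.flatnonzero(filled >= _cap_fraction(g) * gmax)
    cap = int(above[0]) if above.size else g.size  # 0-based crossing index
    floor = max(_FLOOR_MULT * pt.noise, 0.0)
    ok = np.flatnonzero(filled > floor)
    return ok[ok < cap] + 1  # 1-based


def _search_anchor(pt: ProcessedTrace) -> float:
    """Minimum peak signal a searched window must reach.

    The geometric midpoint between the noise floor and the corrected maximum:
    windows anchored below it sit in baseline noise and can score a spuriously
    perfect R^2 with a nonsense slope.
    """
    g = pt.corrected
    if not np.any(np.isfinite(g)):
        return 0.0
    gmax = float(np.nanmax(g))
    floor = max(_FLOOR_MULT * pt.noise, 0.0)
    if floor <= 0 or gmax <= floor:
        return 0.0
    return math.sqrt(floor * gmax)


def _fit_in_range(
    pt: ProcessedTrace, start: int, end: int, anchor: float = 0.0
) -> WindowFit | None:
    cyc = _eligible_cycles(pt)
    sel = cyc[(cyc >= start) & (cyc <= end)]
    if sel.size < 3:
        return None
    vals = pt.corrected[sel - 1]
    if anchor > 0 and float(np.max(vals)) < anchor:
        return None
    slope, intercept, r2 = _linfit(sel.astype(float), np.log10(vals))
    return WindowFit(start, end, slope, intercept, r2, int(sel.size))


def _best_individual_window(
    pt: ProcessedTrace,
    widths: Sequence[int],
    near: tuple[int, int] | None = None,
) -> WindowFit | None:
    """Best-R^2 window of the given widths, preferring placements near ``near``.

    An individually adjusted window should stay an adjustment of the common
    one (>= 2 cycles of overlap): windows that drift away from the threshold
    region extrapolate the Cq and inflate its error.  Only when no overlapping
    placement exists (e.g. a well amplifying many cycles late) does the search
    fall back to the whole trace.
    """
    cycles = pt.trace.cycles
    anchor = _search_anchor(pt)

    def _search(restrict: bool) -> WindowFit | None:
        best: WindowFit | None = None
        for w in widths:
            for s in range(1, cycles - w + 2):
                if restrict and near is not None:
                    overlap = min(s + w - 1, near[1]) - max(s, near[0]) + 1
                    if overlap < 2:
                        continue
                fit = _fit_in_range(pt, s, s + w - 1, anchor)
                if fit is None:
                    continue
                if best is None or fit.r2 > best.r2 + 1e-12:
                    best = fit
        return best

    best = _search(True) if near is not None else _search(False)
    if best is None and near is not None:
        best = _search(False)
    if best is not None:
        best.individual = True
    return best


def find_window_of_linearity(
    ptraces: Sequence[ProcessedTrace],
    width: int = 5,
    widths: tuple[int, int] = (4, 6),
    r2_adjust: float = 0.998,
) -> list[WindowFit | None]:
    """Assign a cycle window to every usable trace of one target group.

    A common window of ``width`` cycles is placed where it covers the most
    traces with the highest mean log-linear R^2; any trace the common window
    fits poorly (R^2 < ``r2_adjust``) or not at all receives an individual
    window of 4-6 cycles maximizing its own R^2.  Traces with no >= 3-point
    placement anywhere come back as None (unusable).
    """
    usable = [pt for pt in ptraces if pt.usable]
    results: list[WindowFit | None] = [None] * len(ptraces)
    if not usable:
        return results

    cycles = max(pt.trace.cycles for pt in usable)
    anchors = [_search_anchor(pt) for pt in usable]
    best_s, best_score = None, (-1, -math.inf)
    for s in range(1, cycles - width + 2):
        fits = [
            _fit_in_range(pt, s, s + width - 1, a)
            for pt, a in zip(usable, anchors)
        ]
        covered = [f for f in fits if f is not None]
        if not covered:
            continue
        score = (len(covered), float(np.mean([f.r2 for f in covered])))
        if score[0] > best_score[0] or (
            score[0] == best_score[0] and score[1] > best_score[1] + 1e-12
        ):
            best_s, best_score = s, score

    indiv_widths = tuple(range(widths[0], widths[1] + 1))
    for i, pt in enumerate(ptraces):
        if not pt.usable:
            continue
        fit = None
        if best_s is not None:
            fit = _fit_in_range(pt, best_s, best_s + width - 1,
                                _search_anchor(pt))
        if fit is None or fit.r2 < r2_adjust:
            near = (
                (best_s, best_s + width - 1) if best_s is not None else None
            )
            indiv = _best_individual_window(pt, indiv_widths, near)
            if indiv is not None and (fit is None or indiv.r2 > fit.r2):
                fit = indiv
        results[i] = fit
    return results


# ---------------------------------------------------------------------------
# efficiency, Cq, N0
# ---------------------------------------------------------------------------


def fit_reaction_efficiency(
    pt: ProcessedTrace, window: tuple[int, int]
) -> WindowFit:
    """Least-squares log10(corrected F) on cycle within ``window``; E = 10**slope."""
    fit = _fit_in_range(pt, int(window[0]), int(window[1]))
    if fit is None:
        raise InvalidParameterError(
            f"window {window} has < 3 usable points for {pt.trace.well}"
        )
    return fit


def determine_cq(
    pt: ProcessedTrace, fit: WindowFit, nt: float
) -> float:
    """Fractional quantification cycle at threshold ``nt``.

    Cq = (log10 Nt - intercept) / slope from the window regression.  Returns
    NaN (an undefined-Cq flag, not an exception) when the threshold falls
    below the trace's noise floor, above its maximum signal, or the solution
    leaves the cycle range.
    """
    if not nt > 0:
        raise InvalidParameterError("threshold must be positive")
    g = pt.corrected
    gmax = float(np.nanmax(g)) if np.any(np.isfinite(g)) else 0.0
    if nt > gmax or nt < _FLOOR_MULT * pt.noise:
        return math.nan
    if fit.slope == 0:
        return math.nan
    cq = (math.log10(nt) - fit.intercept) / fit.slope
    if not (1.0 <= cq <= pt.trace.cycles):
        return math.nan
    return float(cq)


def estimate_n0(cq: float, e_batch: float, nt: float) -> float:
    """Starting concentration N0 = Nt / E**Cq."""
    if not e_batch > 1.0:
        raise InvalidParameterError("batch efficiency must exceed 1")
    if not nt > 0:
        raise InvalidParameterError("threshold must be positive")
    if not math.isfinite(cq):
        return math.nan
    return float(nt / e_batch**cq)


def mean_batch_efficiency(
    efficiencies: Iterable[float], tol: float = 0.05
) -> tuple[float, np.ndarray, bool]:
    """Trimmed mean efficiency for one batch-target.

    Iteratively drops the single worst value deviating more than ``tol``
    (fractionally) from the current mean until all survivors are within the
    band.  Returns (mean, inclusion mask, ok); ok is False when fewer than two
    values survive.
    """
    values = np.asarray(list(efficiencies), dtype=float)
    if values.size < 2:
        raise InvalidParameterError("need >= 2 efficiency values")
    included = np.isfinite(values)
    while True:
        if included.sum() < 2:
            return math.nan, included, False
        mean = float(values[included].mean())
        dev = np.abs(values - mean) / mean
        dev[~included] = -np.inf
        worst = int(np.argmax(dev))
        if dev[worst] > tol:
            included[worst] = False
        else:
            return mean, included, True


def fit_trace(
    trace: FluorescenceTrace,
    nt: float | None = None,
    mode: str = "strict",
    e_batch: float | None = None,
) -> AmplificationFit:
    """Convenience single-trace pipeline: baseline -> window -> E -> Cq -> N0.

    The window is searched individually (no plate context); ``nt`` is needed
    for a Cq, and ``e_batch`` (defaulting to the trace's own E) for N0.
    """
    pt = correct_baseline(trace, mode)
    if not pt.usable:
        return AmplificationFit(
            baseline=pt.baseline, window=None, efficiency=math.nan,
            fit_r2=math.nan, cq=math.nan, n0=math.nan,
            threshold_used=nt if nt is not None else math.nan, usable=False,
        )
    fit = _best_individual_window(pt, (4, 5, 6))
    if fit is None:
        return AmplificationFit(
            baseline=pt.baseline, window=None, efficiency=math.nan,
            fit_r2=math.nan, cq=math.nan, n0=math.nan,
            threshold_used=nt if nt is not None else math.nan, usable=False,
        )
    cq = determine_cq(pt, fit, nt) if nt is not None else math.nan
    e_for_n0 = e_batch if e_batch is not None else fit.efficiency
    n0 = (
        estimate_n0(cq, e_for_n0, nt)
        if nt is not None and math.isfinite(cq) and e_for_n0 > 1
        else math.nan
    )
    return AmplificationFit(
        baseline=pt.baseline, window=(fit.start, fit.end),
        efficiency=fit.efficiency, fit_r2=fit.r2, cq=cq, n0=n0,
        threshold_used=nt if nt is not None else math.nan, usable=True,
        individual_window=True, slope=fit.slope, intercept=fit.intercept,
    )


# ---------------------------------------------------------------------------
# melt curves
# ---------------------------------------------------------------------------


def detect_melt_peaks(
    melt: MeltCurve, standard_peak: float | None = None, tolerance: float = 2.0
) -> tuple[list[float], bool]:
    """Peaks of -dF/dT and a primer-dimer flag.

    Peaks are local maxima of the negative derivative above 10% of its global
    maximum; a peak lying more than ``tolerance`` degC from ``standard_peak``
    raises the dimer flag (dimers melt away from the genuine product, e.g.
    near 87 degC for telomere-reference primer dimers).
    """
    t = melt.temperatures
    f = melt.readings
    if t.size < 10:
        raise InvalidParameterError("melt curve needs >= 10 temperature points")
    if not np.all(np.diff(t) > 0):
        raise InvalidParameterError("temperatures must be strictly ascending")
    deriv = -np.gradient(f, t)
    dmax = float(deriv.max())
    scale = float(np.median(np.abs(deriv))) + 1e-15
    if dmax <= 0 or dmax < 5.0 * scale:
        return [], False
    idx, _ = find_peaks(deriv, height=0.1 * dmax)
    peaks = [float(t[i]) for i in idx]
    dimer = False
    if standard_peak is not None:
        dimer = any(abs(p - standard_peak) > tolerance for p in peaks)
    return peaks, dimer
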