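"""Standard curves and relative telomere length (T/S) quantification.

Three quantification routes are implemented:

* **Pfaffl** — efficiency from the standard-curve slope, ``E = 10**(-1/a)``;
  the amount of target relative to a calibrator is ``E**(Cq_cal - Cq_sample)``.
* **Ruijter** — per-reaction starting concentrations ``N0 = Nt/E**Cq`` from
  the window-of-linearity fits; amounts read off the regression of log10 N0
  on log10 expected amount, ``10**((log10 N0 - b)/a)``.
* **comparative Cq (ddCq)** — efficiency fixed at 2 for both targets,
  ``T/S = 2**(-ddCq)`` with the double difference taken against a calibrator
  sample present in every batch.

T/S = (amount telomere)/(amount reference) is dimensionless and scale-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import InvalidParameterError, _linfit

DDCQ_EFFICIENCY = 2.0  # Livak convention: perfect doubling assumed


@dataclass
class StandardCurve:
    """OLS fit of response on log10 expected DNA amount for one batch-target.

    ``method`` is "cq" (response = mean Cq, slope negative) or "n0"
    (response = mean log10 N0, slope ~ +1 for a well-behaved assay).
    """

    target: str
    batch: str
    method: str
    slope: float
    intercept: float
    r2: float
    points: pd.DataFrame  # columns: amount_ng, x (log10 amount), y (response)
    ldr: tuple[float, float] | None = None

    @property
    def e_from_slope(self) -> float:
        if self.method != "cq":
            return math.nan
        return efficiency_from_slope(self.slope)


@dataclass
class TSEstimate:
    """Replicate-aggregated T/S for one sample under one method."""

    sample: str
    method: str
    n: int
    ts_mean: float
    ts_sd: float
    ts_cv: float
    n_excluded: int = 0
    straggler: bool = False


def fit_standard_curve(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    method: str,
    target: str = "",
    batch: str = "",
) -> StandardCurve:
    """Fit a standard curve from (log10 amount, response) dilution-step means."""
    if method not in ("cq", "n0"):
        raise InvalidParameterError(f"unknown standard-curve method {method!r}")
    if isinstance(points, pd.DataFrame):
        df = points.copy()
    else:
        df = pd.DataFrame(points, columns=["x", "y"])
    df = df.dropna(subset=["x", "y"])
    if df["x"].nunique() < 3:
        raise InvalidParameterError("standard curve needs >= 3 distinct dilutions")
    slope, intercept, r2 = _linfit(df["x"].to_numpy(), df["y"].to_numpy())
    if "amount_ng" not in df.columns:
        df["amount_ng"] = 10.0 ** df["x"]
    return StandardCurve(target, batch, method, slope, intercept, r2,
                         df.reset_index(drop=True))


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency from a Cq standard-curve slope: E = 10**(-1/a)."""
    if slope == 0:
        raise InvalidParameterError("slope must be nonzero")
    return float(10.0 ** (-1.0 / slope))


def efficiency_to_percent(efficiency: float) -> float:
    """Express efficiency as percent amplification per cycle: (E - 1) * 100."""
    if not efficiency > 0:
        raise InvalidParameterError("efficiency must be positive")
    return (efficiency - 1.0) * 100.0


def quantify_pfaffl(
    cq_sample: float, curve: StandardCurve, cq_calibrator: float
) -> float:
    """Amount relative to the calibrator: E_slope ** (Cq_cal - Cq_sample).

    With the calibrator defined at log amount 0 (Cq = intercept), this equals
    10**((Cq_sample - b)/a).
    """
    if curve.method != "cq":
        raise InvalidParameterError("Pfaffl quantification needs a Cq-based curve")
    e = curve.e_from_slope
    if not e > 1:
        raise InvalidParameterError("curve efficiency must exceed 1")
    if not (math.isfinite(cq_sample) and math.isfinite(cq_calibrator)):
        return math.nan
    return float(e ** (cq_calibrator - cq_sample))


def interpolate_amount(cq_or_logn0: float, curve: StandardCurve) -> float:
    """Observed amount (ng) read off a standard curve: 10**((y - b)/a)."""
    if curve.slope == 0:
        raise InvalidParameterError("degenerate standard curve (slope = 0)")
    if not math.isfinite(cq_or_logn0):
        return math.nan
    return float(10.0 ** ((cq_or_logn0 - curve.intercept) / curve.slope))


def quantify_ruijter(log10_n0: float, curve: StandardCurve) -> float:
    """Amount from an N0-based standard curve: 10**((log10 N0 - b)/a)."""
    if curve.method != "n0":
        raise InvalidParameterError("Ruijter quantification needs an N0-based curve")
    return interpolate_amount(log10_n0, curve)


def quantify_ddcq(
    cq_t_sample: float,
    cq_s_sample: float,
    cq_t_calibrator: float,
    cq_s_calibrator: float,
) -> float:
    """Comparative-Cq T/S relative to the calibrator: 2**(-ddCq)."""
    values = (cq_t_sample, cq_s_sample, cq_t_calibrator, cq_s_calibrator)
    if not all(math.isfinite(v) for v in values):
        return math.nan
    ddcq = (cq_t_sample - cq_t_calibrator) - (cq_s_sample - cq_s_calibrator)
    return float(DDCQ_EFFICIENCY ** (-ddcq))


def ts_ratio(t: float, s: float) -> float:
    """Relative telomere length T/S; undefined (NaN) when S is 0 or undefined."""
    if not math.isfinite(t) or not math.isfinite(s) or s == 0:
        return math.nan
    return float(t / s)


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float, float]:
    """Replicate mean, sample SD (n-1) and CV% of defined T/S values."""
    arr = np.asarray([v for v in values if math.isfinite(v)], dtype=float)
    if arr.size == 0:
        return math.nan, math.nan, math.nan
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, math.nan, math.nan
    sd = float(arr.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else math.nan
    return mean, sd, cv
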