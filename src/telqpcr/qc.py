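"""Assay quality control: outlier banding, NTC/LDR checks, precision,
accuracy, robustness and resolution metrics, and the summary scorecard.

The battery mirrors what a careful qPCR validation runs on a serial-dilution
design: Grubbs' single-outlier test with an outlier (<1%) and straggler
(1-5%) band, the no-template-control Cq gap to the most diluted standard,
the linear dynamic range of the standard curve, triplicate Cq SD and
observed-vs-expected regression (precision/accuracy), cross-batch CV of
observed log amounts (robustness), adjacent-dilution t-tests (resolution),
the efficiency-vs-input regression, inter-method correlation of T/S, and a
per-criterion verdict table with an overall call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curves import InvalidParameterError, _linfit


@dataclass(frozen=True)
class QCThresholds:
    """Decision thresholds for the QC battery (units in field names)."""

    grubbs_outlier_alpha: float = 0.01
    grubbs_straggler_alpha: float = 0.05
    ntc_ok_dcq: float = 10.0  # cycles
    ntc_overlap_dcq: float = 0.0  # cycles
    ldr_min_points: int = 3
    ldr_r2_min: float = 0.985
    ldr_max_abs_residual: float = 0.5  # Cq
    efficiency_band: float = 0.05  # fractional deviation tolerated from mean E
    melt_tolerance: float = 2.0  # degC

    def __post_init__(self) -> None:
        if not (0 < self.grubbs_outlier_alpha < self.grubbs_straggler_alpha < 1):
            raise InvalidParameterError(
                "need 0 < outlier alpha < straggler alpha < 1"
            )
        if not self.ntc_ok_dcq > self.ntc_overlap_dcq:
            raise InvalidParameterError("ntc_ok_dcq must exceed ntc_overlap_dcq")


# ---------------------------------------------------------------------------
# Grubbs outlier banding
# ---------------------------------------------------------------------------


@dataclass
class GrubbsResult:
    g: np.ndarray  # per-value |x - mean| / SD
    p: np.ndarray  # two-sided Grubbs p-value per value
    classes: list[str]  # keep | straggler | outlier
    degenerate: bool = False


def grubbs_max_g(n: int) -> float:
    """Largest attainable Grubbs statistic for n values: (n-1)/sqrt(n)."""
    return (n - 1) / math.sqrt(n)


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t distribution (n-2 df)."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return grubbs_max_g(n) * math.sqrt(t * t / (n - 2 + t * t))


def _grubbs_p(g: float, n: int) -> float:
    """Two-sided p of a Grubbs statistic (inversion of the critical value)."""
    denom = (n - 1) ** 2 - n * g * g
    if denom <= 0:
        return 0.0
    t = math.sqrt((n - 2) * n * g * g / denom)
    return float(min(1.0, 2.0 * n * stats.t.sf(t, n - 2)))


def grubbs_classify(
    values: Sequence[float], thresholds: QCThresholds = QCThresholds()
) -> GrubbsResult:
    """Band each value as keep / straggler / outlier by its Grubbs p-value.

    The single-outlier statistic G_i = |x_i - mean| / SD is computed for every
    value, but only the single largest G is eligible for the outlier band in
    one pass (classical Grubbs tests one suspect at a time); any value with
    p in the straggler band is flagged but retained by downstream filters.
    Degenerate inputs (n < 3 or SD = 0) perform no test: everything is kept.
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 3 or not np.all(np.isfinite(arr)):
        finite = arr[np.isfinite(arr)]
        g = np.full(n, math.nan)
        return GrubbsResult(g, np.ones(n), ["keep"] * n, degenerate=True)
    sd = float(arr.std(ddof=1))
    if sd == 0:
        return GrubbsResult(
            np.zeros(n), np.ones(n), ["keep"] * n, degenerate=True
        )
    g = np.abs(arr - arr.mean()) / sd
    p = np.array([_grubbs_p(gi, n) for gi in g])
    classes = []
    imax = int(np.argmax(g))
    for i in range(n):
        if p[i] < thresholds.grubbs_outlier_alpha and i == imax:
            classes.append("outlier")
        elif p[i] < thresholds.grubbs_straggler_alpha:
            classes.append("straggler")
        else:
            classes.append("keep")
    return GrubbsResult(g, p, classes)


def filter_unknown_outliers(
    cq_values: Sequence[float],
    ts_values: Sequence[float],
    observed_ng: Sequence[float],
    ldr: tuple[float, float] | None,
    thresholds: QCThresholds = QCThresholds(),
) -> pd.DataFrame:
    """Per-replicate exclusion flags for one sample's pooled replicate set.

    A replicate is excluded when its interpolated amount falls outside the
    standard curve's linear dynamic range, or when it is the Grubbs outlier
    (p < 1%) of the sample's Cq set or of its T/S set (tested on the log
    scale); stragglers (1-5%) are flagged but retained.  Arrays are aligned
    per replicate; NaNs mean undefined.  A missing LDR is an error — the
    amount check is not optional.
    """
    if ldr is None:
        raise InvalidParameterError("LDR required for outlier filtering")
    cq = np.asarray(list(cq_values), dtype=float)
    ts = np.asarray(list(ts_values), dtype=float)
    ng = np.asarray(list(observed_ng), dtype=float)
    n = cq.size
    if not (ts.size == n and ng.size == n):
        raise InvalidParameterError("replicate arrays must be aligned")
    out_ldr = np.isfinite(ng) & ((ng < ldr[0]) | (ng > ldr[1]))

    def _classes(values: np.ndarray) -> list[str]:
        finite = np.flatnonzero(np.isfinite(values))
        res = grubbs_classify(values[finite], thresholds)
        cls = ["keep"] * values.size
        for pos, c in zip(finite, res.classes):
            cls[pos] = c
        return cls

    cq_cls = _classes(cq)
    with np.errstate(invalid="ignore", divide="ignore"):
        log_ts = np.where(ts > 0, np.log(np.where(ts > 0, ts, 1.0)), np.nan)
    ts_cls = _classes(log_ts)
    excluded = [
        bool(o or c == "outlier" or t == "outlier")
        for o, c, t in zip(out_ldr, cq_cls, ts_cls)
    ]
    straggler = [
        bool(c == "straggler" or t == "straggler")
        for c, t in zip(cq_cls, ts_cls)
    ]
    return pd.DataFrame({
        "out_of_ldr": out_ldr, "cq_class": cq_cls, "ts_class": ts_cls,
        "excluded": excluded, "straggler": straggler,
    })


# ---------------------------------------------------------------------------
# NTC check
# ---------------------------------------------------------------------------


def check_ntc(
    ntc_cqs: Sequence[float],
    most_diluted_standard_cqs: Sequence[float],
    melt_dimer_flag: bool = False,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[float, str]:
    """Cq gap between NTCs and the most diluted standard, with a verdict.

    dCq = mean(NTC Cq) - mean(most diluted standard Cq).  Verdicts:
    ``ok`` when the NTC amplifies >= ntc_ok_dcq cycles later (or not at all),
    ``overlap`` when dCq <= ntc_overlap_dcq, ``borderline`` in between.  An
    overlap explained by a primer-dimer melt peak becomes ``dimer-explained``
    (the signal is not template contamination and does not bias T/S).
    """
    ntc = np.asarray([c for c in ntc_cqs if math.isfinite(c)], dtype=float)
    std = np.asarray(
        [c for c in most_diluted_standard_cqs if math.isfinite(c)], dtype=float
    )
    if ntc.size == 0:
        return math.inf, "ok"  # no NTC amplification at all
    if std.size == 0:
        raise InvalidParameterError("no defined Cq for the most diluted standard")
    dcq = float(ntc.mean() - std.mean())
    if dcq >= thresholds.ntc_ok_dcq:
        verdict = "ok"
    elif dcq <= thresholds.ntc_overlap_dcq:
        verdict = "dimer-explained" if melt_dimer_flag else "overlap"
    else:
        verdict = "borderline"
    return dcq, verdict


# ---------------------------------------------------------------------------
# linear dynamic range
# ---------------------------------------------------------------------------


def determine_ldr(
    steps: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> tuple[tuple[float, float] | None, pd.Series]:
    """Widest contiguous dilution-step run that stays linear.

    ``steps`` has one row per dilution step with columns ``amount_ng`` and
    ``y`` (mean response, typically mean Cq).  A run qualifies when its own
    OLS fit reaches R^2 >= ldr_r2_min with max |residual| <= the residual cap;
    ties go to the run with more steps, then the lower-concentration end.
    Returns (bounds in ng or None, residuals of the full-series fit).
    """
    df = steps.dropna(subset=["amount_ng", "y"]).sort_values("amount_ng")
    if len(df) < thresholds.ldr_min_points:
        raise InvalidParameterError(
            f"need >= {thresholds.ldr_min_points} dilution steps"
        )
    x = np.log10(df["amount_ng"].to_numpy(dtype=float))
    y = df["y"].to_numpy(dtype=float)
    slope, intercept, _ = _linfit(x, y)
    full_resid = pd.Series(y - (intercept + slope * x), index=df.index)

    n = len(df)
    best: tuple[int, int] | None = None
    for i in range(n):
        for j in range(i + thresholds.ldr_min_points, n + 1):
            xs, ys = x[i:j], y[i:j]
            s, b, r2 = _linfit(xs, ys)
            resid = np.abs(ys - (b + s * xs))
            if r2 >= thresholds.ldr_r2_min and resid.max() <= (
                thresholds.ldr_max_abs_residual
            ):
                length = j - i
                if (
                    best is None
                    or length > best[1] - best[0]
                    or (length == best[1] - best[0] and i < best[0])
                ):
                    best = (i, j)
    if best is None:
        return None, full_resid
    amounts = df["amount_ng"].to_numpy(dtype=float)
    return (float(amounts[best[0]]), float(amounts[best[1] - 1])), full_resid


# ---------------------------------------------------------------------------
# precision / accuracy / robustness / resolution
# ---------------------------------------------------------------------------


def precision_metrics(
    cq_triplicates: Sequence[Sequence[float]],
    observed_log: Sequence[float],
    expected_log: Sequence[float],
) -> tuple[float, float]:
    """(mean triplicate Cq SD, R^2 of observed-vs-expected log amounts)."""
    sds = []
    for trip in cq_triplicates:
        arr = np.asarray([v for v in trip if math.isfinite(v)], dtype=float)
        if arr.size >= 2:
            sds.append(float(arr.std(ddof=1)))
    mean_sd = float(np.mean(sds)) if sds else math.nan
    obs = np.asarray(observed_log, dtype=float)
    exp = np.asarray(expected_log, dtype=float)
    keep = np.isfinite(obs) & np.isfinite(exp)
    if keep.sum() >= 3 and np.unique(exp[keep]).size >= 2:
        _, _, r2 = _linfit(exp[keep], obs[keep])
    else:
        r2 = math.nan
    return mean_sd, r2


def accuracy_test(
    observed_log: Sequence[float], expected_log: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS slope of observed on expected log amounts, tested against 1.

    Returns (slope, SE, t, two-tailed p with n-2 df).  A perfectly accurate
    assay has slope 1.
    """
    obs = np.asarray(observed_log, dtype=float)
    exp = np.asarray(expected_log, dtype=float)
    keep = np.isfinite(obs) & np.isfinite(exp)
    obs, exp = obs[keep], exp[keep]
    if obs.size < 3:
        raise InvalidParameterError("need >= 3 points")
    slope, intercept, _ = _linfit(exp, obs)
    n = obs.size
    resid = obs - (intercept + slope * exp)
    sxx = float(((exp - exp.mean()) ** 2).sum())
    mse = float((resid**2).sum()) / (n - 2)
    se = math.sqrt(mse / sxx)
    if se == 0:
        t = 0.0 if slope == 1.0 else math.copysign(math.inf, slope - 1.0)
        p = 1.0 if slope == 1.0 else 0.0
    else:
        t = (slope - 1.0) / se
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return float(slope), float(se), float(t), p


def robustness_cv(
    per_step_values: Mapping[float, Sequence[float]],
) -> tuple[pd.Series, float]:
    """CV% of observed log amounts per dilution step across batches.

    Returns (per-step CV% indexed by expected amount, their average).  CV on
    log-scale values is statistically odd but is the convention followed here.
    """
    out = {}
    for amount, vals in per_step_values.items():
        arr = np.asarray([v for v in vals if math.isfinite(v)], dtype=float)
        if arr.size < 2:
            raise InvalidParameterError("robustness needs >= 2 batches per step")
        mean = arr.mean()
        out[amount] = (
            math.nan if mean == 0 else float(100.0 * arr.std(ddof=1) / mean)
        )
    series = pd.Series(out).sort_index()
    finite = series.dropna()
    return series, float(finite.mean()) if len(finite) else math.nan


def resolution_ttests(
    step_values: Sequence[Sequence[float]], welch: bool = False
) -> list[float]:
    """Two-tailed t-test p-value for each adjacent dilution-step pair.

    Pooled variance by default (Welch selectable).  Conventions for the
    degenerate zero-variance case: equal means -> p = 1, unequal -> p = 0.
    """
    ps = []
    for a, b in zip(step_values, step_values[1:]):
        x = np.asarray([v for v in a if math.isfinite(v)], dtype=float)
        y = np.asarray([v for v in b if math.isfinite(v)], dtype=float)
        if x.size < 2 or y.size < 2:
            raise InvalidParameterError("need >= 2 observations per step")
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            ps.append(1.0 if x.mean() == y.mean() else 0.0)
            continue
        res = stats.ttest_ind(x, y, equal_var=not welch)
        ps.append(float(res.pvalue))
    return ps


def unknown_resolution(
    ts_means: Sequence[float], ts_sds: Sequence[float]
) -> tuple[float, float, float]:
    """(dMinMax, average SD, SD/(dMinMax)%) of the unknowns' T/S estimates."""
    means = np.asarray([v for v in ts_means if math.isfinite(v)], dtype=float)
    if means.size < 2:
        raise InvalidParameterError("need >= 2 samples with defined T/S")
    sds = np.asarray([v for v in ts_sds if math.isfinite(v)], dtype=float)
    dminmax = float(means.max() - means.min())
    avg_sd = float(sds.mean()) if sds.size else math.nan
    ratio = math.nan if dminmax == 0 else 100.0 * avg_sd / dminmax
    return dminmax, avg_sd, ratio


def efficiency_amount_regression(
    efficiencies: Sequence[float], log_amounts: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS of per-reaction E on log10 expected amount: (slope, intercept, R^2, p).

    A significantly negative slope reproduces the efficiency-decay signature
    of overloaded reactions (efficiency falling with template amount).
    """
    e = np.asarray(efficiencies, dtype=float)
    x = np.asarray(log_amounts, dtype=float)
    keep = np.isfinite(e) & np.isfinite(x)
    e, x = e[keep], x[keep]
    if e.size < 3 or np.unique(x).size < 2:
        raise InvalidParameterError("need >= 3 points with >= 2 distinct amounts")
    res = stats.linregress(x, e)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


def intermethod_r2(ts_by_method: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Pairwise squared Pearson correlation (in %) of per-sample T/S vectors."""
    methods = list(ts_by_method)
    mat = pd.DataFrame(index=methods, columns=methods, dtype=float)
    for i, mi in enumerate(methods):
        for j, mj in enumerate(methods):
            a, b = ts_by_method[mi].dropna(), ts_by_method[mj].dropna()
            common = a.index.intersection(b.index)
            if len(common) < 3:
                mat.loc[mi, mj] = math.nan
                continue
            r = stats.pearsonr(a.loc[common], b.loc[common]).statistic
            mat.loc[mi, mj] = 100.0 * r * r
    return mat


# ---------------------------------------------------------------------------
# scorecard
# ---------------------------------------------------------------------------

# verdict -> severity rank; the overall call is the worst rank present
_RANK = {
    "ok": 0, "high": 0, "within-range": 0, "constant": 0, "no-change": 0,
    "few": 0, "dimer-explained": 0,
    "borderline": 1, "intermediate": 1, "many": 1,
    "overlap": 2, "low": 2, "variable": 2, "fail": 2,
    "not-evaluated": -1,
}
_OVERALL = {0: "best", 1: "intermediate", 2: "worst"}


@dataclass
class AssayScorecard:
    """Per-criterion values and verdicts plus the overall assay call."""

    rows: pd.DataFrame  # criterion, target, value, verdict
    overall: str

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "criteria": self.rows.to_dict(orient="records"),
        }


def _band(value: float, cuts: Sequence[tuple[float, str]], default: str,
          reverse: bool = False) -> str:
    """First label whose cut the value satisfies (<= cut; >= cut if reverse)."""
    if value is None or (isinstance(value, float) and not math.isfinite(value)):
        return "not-evaluated"
    for cut, label in cuts:
        if (value >= cut) if reverse else (value <= cut):
            return label
    return default


def build_scorecard(
    metrics: Mapping[str, Mapping],
    thresholds: QCThresholds = QCThresholds(),
) -> AssayScorecard:
    """Assemble the verdict table from the computed QC metrics.

    ``metrics`` holds a dict per target ("telomere", "reference") plus a
    "ts" dict; missing entries are marked not-evaluated.  Verdicts are pure
    functions of the inputs; the documented bands live in docs/methods.md.
    The overall verdict is the worst band across criteria, except that an
    NTC overlap explained by primer dimers is not counted as a failure.
    """
    if not metrics:
        raise InvalidParameterError("empty metrics")
    rows = []

    def add(criterion: str, target: str, value, verdict: str) -> None:
        rows.append(
            {"criterion": criterion, "target": target, "value": value,
             "verdict": verdict}
        )

    for target in ("telomere", "reference"):
        m = metrics.get(target, {})
        frac = m.get("ldr_step_fraction", math.nan)
        if isinstance(frac, float) and math.isnan(frac):
            add("ldr", target, frac, "not-evaluated")
        elif frac <= 0:
            add("ldr", target, frac, "fail")
        else:
            add("ldr", target, frac,
                "within-range" if frac >= 1.0 else "borderline")
        add("ntc", target, m.get("ntc_dcq", math.nan),
            m.get("ntc_verdict", "not-evaluated"))
        add("magnitude_e", target, m.get("e_mean", math.nan),
            _band(m.get("e_mean", math.nan),
                  [(1.80, "high"), (1.60, "intermediate")], "low", reverse=True))
        add("interbatch_e", target, m.get("e_interbatch_sd", math.nan),
            _band(m.get("e_interbatch_sd", math.nan), [(0.05, "constant")],
                  "variable"))
        p = m.get("dilution_e_p", math.nan)
        add("dilution_e", target, p,
            "not-evaluated" if not math.isfinite(p)
            else ("variable" if p < 0.05 else "no-change"))
        add("precision_cq_sd", target, m.get("cq_sd", math.nan),
            _band(m.get("cq_sd", math.nan),
                  [(0.25, "high"), (0.45, "intermediate")], "low"))
        slope = m.get("accuracy_slope", math.nan)
        add("accuracy_slope", target, slope,
            "not-evaluated" if not math.isfinite(slope)
            else _band(abs(slope - 1.0),
                       [(0.03, "high"), (0.08, "intermediate")], "low"))
        add("resolution", target, m.get("resolution_sig_fraction", math.nan),
            _band(m.get("resolution_sig_fraction", math.nan),
                  [(0.999, "high"), (0.66, "intermediate")], "low",
                  reverse=True))

    ts = metrics.get("ts", {})
    add("precision", "ts", ts.get("cv_mean", math.nan),
        _band(ts.get("cv_mean", math.nan),
              [(15.0, "high"), (30.0, "intermediate")], "low"))
    add("accuracy", "ts", ts.get("standards_max_dev", math.nan),
        _band(ts.get("standards_max_dev", math.nan),
              [(0.10, "high"), (0.25, "intermediate")], "low"))
    add("outliers", "ts", ts.get("outlier_fraction", math.nan),
        _band(ts.get("outlier_fraction", math.nan), [(0.05, "few")], "many"))
    add("resolution", "ts", ts.get("sd_dminmax_pct", math.nan),
        _band(ts.get("sd_dminmax_pct", math.nan),
              [(10.0, "high"), (16.0, "intermediate")], "low"))
    add("quantitative_method", "ts", ts.get("intermethod_min_r2", math.nan),
        _band(ts.get("intermethod_min_r2", math.nan),
              [(85.0, "high"), (60.0, "intermediate")], "low", reverse=True))

    df = pd.DataFrame(rows)
    ranks = df["verdict"].map(_RANK)
    worst = int(ranks[ranks >= 0].max()) if (ranks >= 0).any() else 0
    return AssayScorecard(df, _OVERALL[worst])
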