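"""The assay model object and its fitted results.

``TelomereAssay`` wraps one assay's plate data (all batches) plus an
``AnalysisConfig``; ``fit()`` runs the full pipeline — baseline correction,
window of linearity, per-reaction efficiency, Cq and N0, standard curves with
their linear dynamic range, T/S quantification by every configured method,
outlier filtering and the QC scorecard — and returns an ``AssayResults``.

The stages are also exposed as free functions operating on plain DataFrames
(``process_traces``, ``quantify_from_fits``, ``qc_from_outputs``) so the CLI
can run them separately on intermediate TSVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import curves as _curves
from . import quant as _quant
from . import qc as _qc
from .curves import (
    FluorescenceTrace,
    InvalidParameterError,
    MeltCurve,
    correct_baseline,
    determine_cq,
    detect_melt_peaks,
    estimate_n0,
    find_window_of_linearity,
    mean_batch_efficiency,
)
from .io import AnalysisConfig, plate_to_traces, melt_to_curves, read_melt_csv, read_plate_csv, write_reports
from .quant import (
    StandardCurve,
    aggregate_replicates,
    fit_standard_curve,
    interpolate_amount,
    quantify_ddcq,
    quantify_pfaffl,
    quantify_ruijter,
    ts_ratio,
)

_MODE_FOR_METHOD = {
    "pfaffl_lr": "strict",
    "pfaffl_rg": "min",
    "ruijter": "strict",
    "ddcq": "strict",
}

FIT_COLUMNS = [
    "baseline_mode", "batch", "well", "role", "target", "sample", "replicate",
    "expected_ng", "baseline", "noise", "win_start", "win_end",
    "individual_window", "slope", "intercept", "fit_r2", "e", "e_batch",
    "threshold", "cq", "n0", "usable",
]


# ---------------------------------------------------------------------------
# stage 1: traces -> per-well fits
# ---------------------------------------------------------------------------


def _geometric_mean(values: np.ndarray) -> float:
    vals = values[np.isfinite(values) & (values > 0)]
    if vals.size == 0:
        return math.nan
    return float(np.exp(np.mean(np.log(vals))))


def _common_window(fits: Sequence[_curves.WindowFit | None]) -> tuple[int, int] | None:
    counts: dict[tuple[int, int], int] = {}
    for f in fits:
        if f is not None and not f.individual:
            counts[(f.start, f.end)] = counts.get((f.start, f.end), 0) + 1
    if counts:
        return max(counts, key=lambda k: (counts[k], -k[0]))
    starts = [f.start for f in fits if f is not None]
    if not starts:
        return None
    s = int(np.median(starts))
    return (s, s + 4)


def process_traces(
    traces: Sequence[FluorescenceTrace], config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Run baseline/window/efficiency/Cq/N0 for every well.

    Processes under the primary baseline mode and, when the variant is
    enabled, additionally under the min-fluorescence baseline (the kind of
    correction instrument software applies), so the two Pfaffl baseline
    variants can be compared downstream.  The
    fluorescence threshold Nt is chosen per target from the first batch
    (geometric mean of the corrected signal at the common window's endpoints)
    and then frozen for all batches.
    """
    config = config or AnalysisConfig()
    modes = [config.baseline_mode]
    if config.run_rg_variant:
        other = "min" if config.baseline_mode == "strict" else "strict"
        modes.append(other)

    rows = []
    for mode in modes:
        pts = [correct_baseline(t, mode) for t in traces]
        groups: dict[tuple[str, str], list[int]] = {}
        for i, t in enumerate(traces):
            groups.setdefault((t.batch, t.target), []).append(i)

        window_fits: list[_curves.WindowFit | None] = [None] * len(traces)
        for (batch, target), idx in groups.items():
            fits = find_window_of_linearity(
                [pts[i] for i in idx],
                width=config.window_width,
                widths=(config.window_min, config.window_max),
                r2_adjust=config.wol_r2_adjust,
            )
            for i, f in zip(idx, fits):
                window_fits[i] = f

        # threshold per target: user-specified, else from the first batch
        nt_by_target: dict[str, float] = dict(config.thresholds)
        batches = sorted({t.batch for t in traces})
        for target in sorted({t.target for t in traces}):
            if target in nt_by_target:
                continue
            for batch in batches:
                idx = groups.get((batch, target), [])
                cw = _common_window([window_fits[j] for j in idx])
                if cw is None:
                    continue
                vals = []
                for i in idx:
                    if window_fits[i] is None or not pts[i].usable:
                        continue
                    g = pts[i].corrected
                    for c in cw:
                        if 1 <= c <= g.size and np.isfinite(g[c - 1]):
                            vals.append(g[c - 1])
                if vals:
                    nt_by_target[target] = _geometric_mean(np.asarray(vals))
                    break

        # batch-level efficiencies then per-well Cq/N0
        for (batch, target), idx in groups.items():
            nt = nt_by_target.get(target, math.nan)
            per_e, cqs = {}, {}
            for i in idx:
                f = window_fits[i]
                if f is None:
                    cqs[i] = math.nan
                    continue
                cqs[i] = (
                    determine_cq(pts[i], f, nt) if math.isfinite(nt) else math.nan
                )
                if traces[i].role != "ntc" and pts[i].usable:
                    per_e[i] = f.efficiency
            e_batch = math.nan
            if len(per_e) >= 2:
                e_batch, _, ok = mean_batch_efficiency(
                    list(per_e.values()), tol=config.qc.efficiency_band
                )
                if not ok:
                    e_batch = math.nan
            for i in idx:
                t = traces[i]
                f = window_fits[i]
                n0 = (
                    estimate_n0(cqs[i], e_batch, nt)
                    if f is not None and math.isfinite(e_batch)
                    and math.isfinite(nt) and e_batch > 1
                    else math.nan
                )
                rows.append({
                    "baseline_mode": mode, "batch": t.batch, "well": t.well,
                    "role": t.role, "target": t.target, "sample": t.sample,
                    "replicate": t.replicate, "expected_ng": t.expected_ng,
                    "baseline": pts[i].baseline, "noise": pts[i].noise,
                    "win_start": f.start if f else np.nan,
                    "win_end": f.end if f else np.nan,
                    "individual_window": bool(f.individual) if f else False,
                    "slope": f.slope if f else np.nan,
                    "intercept": f.intercept if f else np.nan,
                    "fit_r2": f.r2 if f else np.nan,
                    "e": f.efficiency if f else np.nan,
                    "e_batch": e_batch, "threshold": nt,
                    "cq": cqs[i], "n0": n0,
                    "usable": bool(pts[i].usable and f is not None),
                })
    df = pd.DataFrame(rows, columns=FIT_COLUMNS)
    return df.sort_values(
        ["baseline_mode", "batch", "target", "well"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# stage 2: fits -> standard curves and T/S
# ---------------------------------------------------------------------------


def _default_calibrator(fits: pd.DataFrame) -> str:
    std = fits.loc[fits["role"] == "standard", ["sample", "expected_ng"]]
    if std.empty:
        raise InvalidParameterError("no standard wells: cannot pick a calibrator")
    amounts = std.drop_duplicates().sort_values("expected_ng", ascending=False)
    mid = len(amounts) // 2
    return str(amounts.iloc[mid]["sample"])


def _step_means(group: pd.DataFrame) -> pd.DataFrame:
    """Per-dilution-step mean Cq and mean log10 N0 over usable standard wells."""
    std = group[(group["role"] == "standard") & group["usable"]]
    rows = []
    for amount, grp in std.groupby("expected_ng"):
        cq = grp["cq"].dropna()
        n0 = grp["n0"].dropna()
        n0 = n0[n0 > 0]
        rows.append({
            "amount_ng": float(amount),
            "x": math.log10(float(amount)),
            "mean_cq": cq.mean() if len(cq) else math.nan,
            "mean_log_n0": np.log10(n0).mean() if len(n0) else math.nan,
            "n": len(grp),
        })
    cols = ["amount_ng", "x", "mean_cq", "mean_log_n0", "n"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols).sort_values(
        "amount_ng"
    ).reset_index(drop=True)


@dataclass
class _BatchCurves:
    cq: StandardCurve
    n0: StandardCurve | None
    ldr: tuple[float, float] | None
    steps: pd.DataFrame


def _fit_batch_curves(
    group: pd.DataFrame, qct: _qc.QCThresholds, target: str, batch: str
) -> _BatchCurves | None:
    steps = _step_means(group)
    if steps.empty:
        return None
    steps_cq = steps.rename(columns={"mean_cq": "y"})[
        ["amount_ng", "x", "y"]
    ].dropna()
    if steps_cq["x"].nunique() < 3:
        return None
    ldr, _ = determine_ldr_safe(steps_cq, qct)
    if ldr is not None:
        keep = (steps_cq["amount_ng"] >= ldr[0]) & (steps_cq["amount_ng"] <= ldr[1])
        fit_pts = steps_cq[keep]
    else:
        fit_pts = steps_cq
    if fit_pts["x"].nunique() < 3:
        fit_pts = steps_cq
    cq_curve = fit_standard_curve(
        fit_pts.rename(columns={"y": "y"}), "cq", target=target, batch=batch
    )
    cq_curve.ldr = ldr
    n0_curve = None
    steps_n0 = steps.rename(columns={"mean_log_n0": "y"})[
        ["amount_ng", "x", "y"]
    ].dropna()
    if ldr is not None:
        keep = (steps_n0["amount_ng"] >= ldr[0]) & (steps_n0["amount_ng"] <= ldr[1])
        if keep.sum() >= 3:
            steps_n0 = steps_n0[keep]
    if steps_n0["x"].nunique() >= 3:
        n0_curve = fit_standard_curve(steps_n0, "n0", target=target, batch=batch)
        n0_curve.ldr = ldr
    return _BatchCurves(cq_curve, n0_curve, ldr, steps)


def determine_ldr_safe(steps_cq: pd.DataFrame, qct: _qc.QCThresholds):
    try:
        return _qc.determine_ldr(steps_cq, qct)
    except InvalidParameterError:
        return None, None


def quantify_from_fits(
    fits: pd.DataFrame, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, pd.DataFrame], pd.DataFrame]:
    """Standard curves and per-sample T/S for every configured method.

    Returns (standard-curve table, per-method sample T/S tables, per-method
    unknown well tables with exclusion flags, standards observed-amount
    table used by the QC stage).
    """
    config = config or AnalysisConfig()
    qct = config.qc
    calibrator = config.calibrator or _default_calibrator(fits)

    curve_rows = []
    curves: dict[tuple[str, str, str], _BatchCurves] = {}
    for (mode, batch, target), group in fits.groupby(
        ["baseline_mode", "batch", "target"]
    ):
        bc = _fit_batch_curves(group, qct, target, batch)
        if bc is None:
            continue
        curves[(mode, batch, target)] = bc
        for curve in (bc.cq, bc.n0):
            if curve is None:
                continue
            curve_rows.append({
                "baseline_mode": mode, "batch": batch, "target": target,
                "method": curve.method, "slope": curve.slope,
                "intercept": curve.intercept, "r2": curve.r2,
                "e_from_slope": curve.e_from_slope,
                "ldr_min_ng": bc.ldr[0] if bc.ldr else np.nan,
                "ldr_max_ng": bc.ldr[1] if bc.ldr else np.nan,
            })
    curves_df = pd.DataFrame(curve_rows).sort_values(
        ["baseline_mode", "batch", "target", "method"]
    ).reset_index(drop=True)

    # calibrator Cq per (mode, batch, target)
    cal_cq: dict[tuple[str, str, str], float] = {}
    for (mode, batch, target), group in fits.groupby(
        ["baseline_mode", "batch", "target"]
    ):
        sel = group[(group["sample"] == calibrator) & group["usable"]]
        cal_cq[(mode, batch, target)] = float(sel["cq"].dropna().mean())

    # standards observed amounts (QC inputs), primary mode, Pfaffl + Ruijter
    obs_rows = []
    primary = config.baseline_mode
    for (mode, batch, target), group in fits.groupby(
        ["baseline_mode", "batch", "target"]
    ):
        bc = curves.get((mode, batch, target))
        if bc is None:
            continue
        std = group[(group["role"] == "standard") & group["usable"]]
        for r in std.itertuples(index=False):
            obs_p = interpolate_amount(r.cq, bc.cq)
            obs_r = (
                quantify_ruijter(math.log10(r.n0), bc.n0)
                if bc.n0 is not None and math.isfinite(r.n0) and r.n0 > 0
                else math.nan
            )
            obs_rows.append({
                "baseline_mode": mode, "batch": batch, "target": target,
                "sample": r.sample, "replicate": r.replicate,
                "expected_ng": r.expected_ng, "cq": r.cq, "e": r.e,
                "obs_ng_pfaffl": obs_p, "obs_ng_ruijter": obs_r,
            })
    observed = pd.DataFrame(obs_rows)

    ts_tables: dict[str, pd.DataFrame] = {}
    well_tables: dict[str, pd.DataFrame] = {}
    for method in config.methods:
        mode = _MODE_FOR_METHOD[method]
        sub = fits[fits["baseline_mode"] == mode]
        if sub.empty:
            continue
        wells = _method_well_table(sub, curves, cal_cq, mode, method, qct)
        well_tables[method] = wells
        ts_tables[method] = _aggregate_samples(wells, method, qct)
    return curves_df, ts_tables, well_tables, observed


def _pooled_cq_outliers(unk: pd.DataFrame, qct) -> set[tuple[str, str]]:
    """Wells whose Cq is a Grubbs outlier within the sample's pooled set.

    Pooling a sample's per-target Cq values across batches (n = replicates x
    batches) gives the single-outlier test real power; at triplicate scope the
    1% band can only fire on degenerate near-coincidences.
    """
    out: set[tuple[str, str]] = set()
    for (sample, target), grp in unk.groupby(["sample", "target"]):
        cqs = grp["cq"].to_numpy(dtype=float)
        finite = np.flatnonzero(np.isfinite(cqs))
        res = _qc.grubbs_classify(cqs[finite], qct)
        for pos, cls in zip(finite, res.classes):
            if cls == "outlier":
                row = grp.iloc[pos]
                out.add((row["batch"], row["well"]))
    return out


def _method_well_table(fits, curves, cal_cq, mode, method, qct) -> pd.DataFrame:
    unk = fits[fits["role"] == "unknown"]
    pooled_out = _pooled_cq_outliers(unk, qct)
    rows = []
    for (batch, sample), grp in unk.groupby(["batch", "sample"]):
        tel = grp[grp["target"] == "telomere"].set_index("replicate")
        ref = grp[grp["target"] == "reference"].set_index("replicate")
        # triplicate-level Grubbs: straggler-grade flag only (n = 3 has no
        # power for the 1% band); exclusion-grade calls come from the pooled
        # per-sample sets
        flags: dict[tuple[str, int], dict] = {}
        for target, tdf in (("telomere", tel), ("reference", ref)):
            cqs = tdf["cq"].to_numpy(dtype=float)
            finite_pos = np.flatnonzero(np.isfinite(cqs))
            res = _qc.grubbs_classify(cqs[finite_pos], qct)
            cls_by_pos = dict(zip(finite_pos, res.classes))
            bc = curves.get((mode, batch, target))
            for pos, (rep, r) in enumerate(tdf.iterrows()):
                cls = cls_by_pos.get(pos, "keep")
                if cls == "outlier":
                    cls = "straggler"  # triplicate scope never excludes
                if (batch, r["well"]) in pooled_out:
                    cls = "outlier"
                obs_ng = math.nan
                if bc is not None:
                    if method == "ruijter" and bc.n0 is not None:
                        obs_ng = (
                            quantify_ruijter(math.log10(r["n0"]), bc.n0)
                            if math.isfinite(r["n0"]) and r["n0"] > 0
                            else math.nan
                        )
                    else:
                        obs_ng = interpolate_amount(r["cq"], bc.cq)
                out_ldr = False
                if bc is not None and bc.ldr is not None and math.isfinite(obs_ng):
                    out_ldr = not (bc.ldr[0] <= obs_ng <= bc.ldr[1])
                flags[(target, rep)] = {
                    "cq": r["cq"], "n0": r["n0"], "well": r["well"],
                    "obs_ng": obs_ng, "out_of_ldr": bool(out_ldr),
                    "cq_class": cls, "usable": bool(r["usable"]),
                }
        reps = sorted(set(tel.index) | set(ref.index))
        for rep in reps:
            ft = flags.get(("telomere", rep))
            fr = flags.get(("reference", rep))
            if ft is None or fr is None:
                continue
            t_amt, s_amt = math.nan, math.nan
            bct = curves.get((mode, batch, "telomere"))
            bcr = curves.get((mode, batch, "reference"))
            if method in ("pfaffl_lr", "pfaffl_rg"):
                if bct is not None:
                    t_amt = quantify_pfaffl(
                        ft["cq"], bct.cq, cal_cq.get((mode, batch, "telomere"), math.nan)
                    )
                if bcr is not None:
                    s_amt = quantify_pfaffl(
                        fr["cq"], bcr.cq, cal_cq.get((mode, batch, "reference"), math.nan)
                    )
            elif method == "ruijter":
                t_amt, s_amt = ft["obs_ng"], fr["obs_ng"]
            elif method == "ddcq":
                pass
            if method == "ddcq":
                ts = quantify_ddcq(
                    ft["cq"], fr["cq"],
                    cal_cq.get((mode, batch, "telomere"), math.nan),
                    cal_cq.get((mode, batch, "reference"), math.nan),
                )
            else:
                ts = ts_ratio(t_amt, s_amt)
            excluded = (
                ft["out_of_ldr"] or fr["out_of_ldr"]
                or ft["cq_class"] == "outlier" or fr["cq_class"] == "outlier"
                or not (ft["usable"] and fr["usable"])
            )
            rows.append({
                "batch": batch, "sample": sample, "replicate": rep,
                "well_t": ft["well"], "well_s": fr["well"],
                "cq_t": ft["cq"], "cq_s": fr["cq"],
                "obs_ng_t": ft["obs_ng"], "obs_ng_s": fr["obs_ng"],
                "out_of_ldr": bool(ft["out_of_ldr"] or fr["out_of_ldr"]),
                "out_of_ldr_t": ft["out_of_ldr"], "out_of_ldr_s": fr["out_of_ldr"],
                "cq_outlier_t": ft["cq_class"] == "outlier",
                "cq_outlier_s": fr["cq_class"] == "outlier",
                "cq_straggler": (
                    ft["cq_class"] == "straggler" or fr["cq_class"] == "straggler"
                ),
                "t": t_amt, "s": s_amt, "ts": ts,
                "excluded_well": bool(excluded),
                "ts_outlier": False, "ts_straggler": False,
            })
    cols = ["batch", "sample", "replicate", "well_t", "well_s", "cq_t", "cq_s",
            "obs_ng_t", "obs_ng_s", "out_of_ldr", "out_of_ldr_t", "out_of_ldr_s",
            "cq_outlier_t", "cq_outlier_s", "cq_straggler", "t", "s", "ts",
            "excluded_well", "ts_outlier", "ts_straggler"]
    wells = pd.DataFrame(rows, columns=cols)
    if wells.empty:
        return wells

    # Grubbs across each sample's T/S replicates pooled over batches; tested
    # on the log scale because T/S noise is multiplicative (a Gaussian test on
    # the raw right-skewed ratios over-flags the upper tail)
    for sample, grp in wells.groupby("sample"):
        ok = grp[~grp["excluded_well"] & np.isfinite(grp["ts"]) & (grp["ts"] > 0)]
        if len(ok) < 3:
            continue
        res = _qc.grubbs_classify(np.log(ok["ts"].to_numpy()), qct)
        for idx, cls in zip(ok.index, res.classes):
            if cls == "outlier":
                wells.loc[idx, "ts_outlier"] = True
            elif cls == "straggler":
                wells.loc[idx, "ts_straggler"] = True
    return wells


def _aggregate_samples(wells: pd.DataFrame, method: str, qct) -> pd.DataFrame:
    cols = ["sample", "method", "n", "ts", "sd", "cv", "n_excluded",
            "straggler"]
    if wells.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for sample, grp in wells.groupby("sample"):
        kept = grp[~grp["excluded_well"] & ~grp["ts_outlier"]]
        ts_vals = kept["ts"].to_numpy(dtype=float)
        mean, sd, cv = aggregate_replicates(ts_vals)
        rows.append({
            "sample": sample, "method": method,
            "n": int(np.isfinite(ts_vals).sum()),
            "ts": mean, "sd": sd, "cv": cv,
            "n_excluded": int(
                (grp["excluded_well"] | grp["ts_outlier"]).sum()
            ),
            "straggler": bool(
                kept["ts_straggler"].any() or kept["cq_straggler"].any()
            ),
        })
    return pd.DataFrame(rows, columns=cols).sort_values(
        "sample"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# stage 3: QC metrics and scorecard
# ---------------------------------------------------------------------------


def qc_from_outputs(
    fits: pd.DataFrame,
    curves_df: pd.DataFrame,
    ts_tables: Mapping[str, pd.DataFrame],
    well_tables: Mapping[str, pd.DataFrame],
    observed: pd.DataFrame,
    melts: Sequence[MeltCurve] | None = None,
    config: AnalysisConfig | None = None,
) -> tuple[dict, _qc.AssayScorecard]:
    """Compute the QC battery and assemble the scorecard."""
    config = config or AnalysisConfig()
    qct = config.qc
    primary_mode = config.baseline_mode
    primary_method = config.primary_method
    fits_p = fits[fits["baseline_mode"] == primary_mode]

    # melt: dimer flag per target's NTC wells
    dimer_by_target = {"telomere": False, "reference": False}
    melt_peaks_by_well: dict[tuple[str, str], list[float]] = {}
    if melts:
        well_meta = fits_p.drop_duplicates(subset=["batch", "well"]).set_index(
            ["batch", "well"]
        )
        std_peaks = []
        ntc_curves = []
        for mc in melts:
            key = (mc.batch, mc.well)
            if key not in well_meta.index:
                continue
            meta = well_meta.loc[key]
            peaks, _ = detect_melt_peaks(mc, None, qct.melt_tolerance)
            melt_peaks_by_well[key] = peaks
            if meta["role"] == "standard":
                std_peaks.extend(peaks)
            elif meta["role"] == "ntc":
                ntc_curves.append((mc, meta["target"]))
        standard_peak = (
            config.melt_product_tm
            if config.melt_product_tm is not None
            else (float(np.median(std_peaks)) if std_peaks else None)
        )
        if standard_peak is not None:
            for mc, target in ntc_curves:
                _, dimer = detect_melt_peaks(mc, standard_peak, qct.melt_tolerance)
                if dimer:
                    dimer_by_target[target] = True

    metrics: dict = {"ts": {}, "robustness": {}, "thresholds": dict(qct.__dict__)}
    for target in ("telomere", "reference"):
        sub = fits_p[fits_p["target"] == target]
        if sub.empty:
            continue
        m: dict = {}
        tcurves = curves_df[
            (curves_df["baseline_mode"] == primary_mode)
            & (curves_df["target"] == target)
            & (curves_df["method"] == "cq")
        ]
        std = sub[(sub["role"] == "standard")]
        n_steps = std["expected_ng"].nunique()
        # LDR coverage
        fracs = []
        for r in tcurves.itertuples(index=False):
            if math.isfinite(r.ldr_min_ng):
                amounts = np.sort(std["expected_ng"].unique())
                inside = (amounts >= r.ldr_min_ng) & (amounts <= r.ldr_max_ng)
                fracs.append(inside.mean())
            else:
                fracs.append(0.0)
        m["ldr_step_fraction"] = float(np.mean(fracs)) if fracs else math.nan

        # NTC
        ntc_cq = sub[(sub["role"] == "ntc")]["cq"].to_numpy(dtype=float)
        min_amount = std["expected_ng"].min()
        dilute_cq = std[std["expected_ng"] == min_amount]["cq"].to_numpy(dtype=float)
        try:
            dcq, verdict = _qc.check_ntc(
                ntc_cq, dilute_cq, dimer_by_target[target], qct
            )
        except InvalidParameterError:
            dcq, verdict = math.nan, "not-evaluated"
        m["ntc_dcq"], m["ntc_verdict"] = dcq, verdict

        # efficiency magnitude / inter-batch spread (trimmed batch means)
        eb = sub.drop_duplicates(subset=["batch"])["e_batch"].dropna()
        m["e_mean"] = float(eb.mean()) if len(eb) else math.nan
        m["e_interbatch_sd"] = float(eb.std(ddof=1)) if len(eb) >= 2 else 0.0
        sc_e = tcurves["e_from_slope"].dropna()
        m["e_from_slope_mean"] = float(sc_e.mean()) if len(sc_e) else math.nan

        # efficiency vs amount
        stdu = std[std["usable"]]
        try:
            slope_e, _, r2_e, p_e = _qc.efficiency_amount_regression(
                stdu["e"].to_numpy(), np.log10(stdu["expected_ng"].to_numpy())
            )
            m["dilution_e_slope"], m["dilution_e_r2"], m["dilution_e_p"] = (
                slope_e, r2_e, p_e
            )
        except InvalidParameterError:
            m["dilution_e_p"] = math.nan

        # precision / accuracy on observed vs expected log amounts (Pfaffl)
        obs_t = observed[
            (observed["baseline_mode"] == primary_mode)
            & (observed["target"] == target)
        ]
        trips = [
            grp["cq"].to_numpy(dtype=float)
            for _, grp in stdu.groupby(["batch", "expected_ng"])
        ]
        obs_log = np.log10(obs_t["obs_ng_pfaffl"].to_numpy(dtype=float))
        exp_log = np.log10(obs_t["expected_ng"].to_numpy(dtype=float))
        m["cq_sd"], m["precision_r2"] = _qc.precision_metrics(
            trips, obs_log, exp_log
        )
        try:
            slope, se, tstat, p = _qc.accuracy_test(obs_log, exp_log)
            m["accuracy_slope"], m["accuracy_se"] = slope, se
            m["accuracy_t"], m["accuracy_p"] = tstat, p
        except InvalidParameterError:
            m["accuracy_slope"] = math.nan

        # robustness + resolution over per-batch mean observed log amounts
        per_step: dict[float, list[float]] = {}
        for (batch, amount), grp in obs_t.groupby(["batch", "expected_ng"]):
            vals = np.log10(grp["obs_ng_pfaffl"].to_numpy(dtype=float))
            vals = vals[np.isfinite(vals)]
            if vals.size:
                per_step.setdefault(float(amount), []).append(float(vals.mean()))
        n_batches = sub["batch"].nunique()
        if n_batches >= 2 and per_step:
            try:
                per_step_cv, avg_cv = _qc.robustness_cv(per_step)
                metrics["robustness"][target] = {
                    "per_step_cv": {f"{k:g}": v for k, v in per_step_cv.items()},
                    "average_cv": avg_cv,
                }
            except InvalidParameterError:
                pass
            steps_sorted = sorted(per_step, reverse=True)
            try:
                ps = _qc.resolution_ttests([per_step[a] for a in steps_sorted])
                m["resolution_p"] = ps
                m["resolution_sig_fraction"] = float(
                    np.mean([p < 0.05 for p in ps])
                ) if ps else math.nan
            except InvalidParameterError:
                m["resolution_sig_fraction"] = math.nan
        else:
            m["resolution_sig_fraction"] = math.nan
        metrics[target] = m

    # T/S-level metrics from the primary method
    ts_m: dict = {}
    primary_tbl = ts_tables.get(primary_method)
    wells = well_tables.get(primary_method)
    if primary_tbl is not None and len(primary_tbl):
        cv = primary_tbl["cv"].dropna()
        ts_m["cv_mean"] = float(cv.mean()) if len(cv) else math.nan
        try:
            dmm, avg_sd, ratio = _qc.unknown_resolution(
                primary_tbl["ts"].to_numpy(), primary_tbl["sd"].to_numpy()
            )
            ts_m["dminmax"], ts_m["avg_sd"], ts_m["sd_dminmax_pct"] = (
                dmm, avg_sd, ratio
            )
        except InvalidParameterError:
            pass
    if wells is not None and len(wells):
        n_total = len(wells)
        n_out = int((wells["excluded_well"] | wells["ts_outlier"]).sum())
        ts_m["outlier_fraction"] = n_out / n_total if n_total else math.nan

    # standards T/S constancy across dilution steps (accuracy of the ratio)
    ts_m["standards_max_dev"] = _standards_ts_dev(
        fits_p, curves_df, config
    )

    # inter-method agreement
    vectors = {
        meth: tbl.set_index("sample")["ts"]
        for meth, tbl in ts_tables.items()
        if len(tbl)
    }
    if len(vectors) >= 2:
        mat = _qc.intermethod_r2(vectors)
        off = mat.to_numpy()[~np.eye(len(mat), dtype=bool)]
        off = off[np.isfinite(off)]
        ts_m["intermethod_min_r2"] = float(off.min()) if off.size else math.nan
        metrics["intermethod_r2"] = {
            mi: {mj: (None if pd.isna(mat.loc[mi, mj]) else float(mat.loc[mi, mj]))
                 for mj in mat.columns}
            for mi in mat.index
        }
    metrics["ts"] = ts_m
    scorecard = _qc.build_scorecard(metrics, qct)
    return metrics, scorecard


def _standards_ts_dev(fits_p, curves_df, config) -> float:
    """Non-constancy of the standards' T/S across dilution steps.

    The pooled standard has the same relative telomere content at every
    dilution, so its T/S should be flat across steps; a trend (e.g. from
    template-dependent efficiency) shows up as a step-mean deviating from the
    overall mean.  Ratios are pooled over batches per step and normalized by
    their grand mean, so calibrator-scale noise does not masquerade as
    inaccuracy; returns the max relative deviation.
    """
    sub = fits_p[(fits_p["role"] == "standard") & fits_p["usable"]]
    if sub.empty:
        return math.nan
    ratios = []
    for batch, grp in sub.groupby("batch"):
        tel = grp[grp["target"] == "telomere"]
        ref = grp[grp["target"] == "reference"]
        crv = {}
        for target in ("telomere", "reference"):
            c = curves_df[
                (curves_df["baseline_mode"] == config.baseline_mode)
                & (curves_df["batch"] == batch)
                & (curves_df["target"] == target)
                & (curves_df["method"] == "cq")
            ]
            if c.empty:
                crv = None
                break
            crv[target] = c.iloc[0]
        if not crv:
            continue
        merged = tel.merge(
            ref, on=["expected_ng", "replicate"], suffixes=("_t", "_s")
        )
        if merged.empty:
            continue
        t_amt = 10.0 ** (
            (merged["cq_t"] - crv["telomere"]["intercept"])
            / crv["telomere"]["slope"]
        )
        s_amt = 10.0 ** (
            (merged["cq_s"] - crv["reference"]["intercept"])
            / crv["reference"]["slope"]
        )
        ratios.append(
            pd.DataFrame(
                {"expected_ng": merged["expected_ng"], "ratio": t_amt / s_amt}
            )
        )
    if not ratios:
        return math.nan
    pooled = pd.concat(ratios)
    pooled = pooled[np.isfinite(pooled["ratio"])]
    if pooled.empty:
        return math.nan
    grand = float(pooled["ratio"].mean())
    if grand == 0:
        return math.nan
    step_means = pooled.groupby("expected_ng")["ratio"].mean()
    return float((step_means / grand - 1.0).abs().max())


# ---------------------------------------------------------------------------
# model facade
# ---------------------------------------------------------------------------


class TelomereAssay:
    """A relative telomere length qPCR assay to be fitted.

    Parameters
    ----------
    plate : DataFrame
        Long-format plate table (see ``telqpcr.io.PLATE_COLUMNS``).
    melt : DataFrame, optional
        Long-format melt table.
    config : AnalysisConfig, optional
    """

    def __init__(self, plate: pd.DataFrame, melt: pd.DataFrame | None = None,
                 config: AnalysisConfig | None = None):
        self.plate = plate
        self.melt = melt
        self.config = config or AnalysisConfig()
        self.traces = plate_to_traces(plate)
        self.melts = melt_to_curves(melt) if melt is not None else []

    @classmethod
    def from_dataframe(cls, plate, melt=None, config=None) -> "TelomereAssay":
        return cls(plate, melt, config)

    @classmethod
    def from_csv(cls, plate_path, melt_path=None, config=None) -> "TelomereAssay":
        plate = read_plate_csv(plate_path)
        melt = read_melt_csv(melt_path) if melt_path else None
        return cls(plate, melt, config)

    @classmethod
    def from_simulation(cls, sim, config=None) -> "TelomereAssay":
        plate, melt = sim.to_frames()
        return cls(plate, melt, config)

    def fit(self) -> "AssayResults":
        fits = process_traces(self.traces, self.config)
        curves_df, ts_tables, well_tables, observed = quantify_from_fits(
            fits, self.config
        )
        metrics, scorecard = qc_from_outputs(
            fits, curves_df, ts_tables, well_tables, observed,
            self.melts, self.config,
        )
        return AssayResults(
            model=self, fits=fits, standard_curves=curves_df,
            ts_tables=ts_tables, well_tables=well_tables, observed=observed,
            qc_metrics=metrics, scorecard=scorecard, config=self.config,
        )


@dataclass
class AssayResults:
    """Fitted pipeline outputs for one assay."""

    model: TelomereAssay
    fits: pd.DataFrame
    standard_curves: pd.DataFrame
    ts_tables: dict[str, pd.DataFrame]
    well_tables: dict[str, pd.DataFrame]
    observed: pd.DataFrame
    qc_metrics: dict
    scorecard: _qc.AssayScorecard
    config: AnalysisConfig

    @property
    def ts_summary(self) -> pd.DataFrame:
        """Per-method summary of the unknowns' T/S distribution."""
        rows = []
        for method, tbl in sorted(self.ts_tables.items()):
            ts = tbl["ts"].dropna()
            sd = tbl["sd"].dropna()
            cv = tbl["cv"].dropna()
            if not len(ts):
                continue
            dmm = float(ts.max() - ts.min())
            rows.append({
                "method": method, "n": int(len(ts)),
                "ts_av": float(ts.mean()), "ts_min": float(ts.min()),
                "ts_max": float(ts.max()), "dminmax": dmm,
                "sd_av": float(sd.mean()) if len(sd) else math.nan,
                "cv_av": float(cv.mean()) if len(cv) else math.nan,
                "sd_dminmax_pct": (
                    100.0 * float(sd.mean()) / dmm
                    if dmm > 0 and len(sd) else math.nan
                ),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Relative telomere length assay — fit summary",
                 "=" * 46, ""]
        sc = self.standard_curves
        sc = sc[sc["method"] == "cq"]
        lines.append("Standard curves (Cq-based):")
        for r in sc.itertuples(index=False):
            ldr = (
                f"{r.ldr_min_ng:g}-{r.ldr_max_ng:g} ng"
                if math.isfinite(r.ldr_min_ng) else "none"
            )
            lines.append(
                f"  {r.batch:>4} {r.target:<9} [{r.baseline_mode}] "
                f"slope={r.slope:7.4f}  E={r.e_from_slope:5.3f}  "
                f"R2={r.r2:6.4f}  LDR={ldr}"
            )
        lines.append("")
        summary = self.ts_summary
        if len(summary):
            lines.append("T/S of unknowns per quantification method:")
            lines.append(summary.to_string(index=False, float_format="%.3f"))
            lines.append("")
        lines.append("QC scorecard:")
        for r in self.scorecard.rows.itertuples(index=False):
            val = f"{r.value:.4g}" if isinstance(r.value, float) and math.isfinite(r.value) else "-"
            lines.append(
                f"  {r.criterion:<20} {r.target:<9} {val:>10}  {r.verdict}"
            )
        lines.append(f"Overall: {self.scorecard.overall}")
        return "\n".join(lines)

    def save(self, outdir) -> list[Path]:
        return write_reports(self, outdir)

    # -- plotting ----------------------------------------------------------
    def plot_standard_curve(self, target: str, batch: str, ax=None):
        """Expected log amount vs mean Cq with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.fits[
            (self.fits["baseline_mode"] == self.config.baseline_mode)
            & (self.fits["target"] == target)
            & (self.fits["batch"] == batch)
            & (self.fits["role"] == "standard")
        ]
        x = np.log10(sub["expected_ng"].to_numpy(dtype=float))
        ax.scatter(x, sub["cq"], s=18)
        crv = self.standard_curves[
            (self.standard_curves["baseline_mode"] == self.config.baseline_mode)
            & (self.standard_curves["target"] == target)
            & (self.standard_curves["batch"] == batch)
            & (self.standard_curves["method"] == "cq")
        ]
        if len(crv):
            r = crv.iloc[0]
            xs = np.linspace(np.nanmin(x), np.nanmax(x), 50)
            ax.plot(xs, r["intercept"] + r["slope"] * xs, "k-")
            ax.set_title(
                f"{target} {batch}: slope {r['slope']:.3f}, "
                f"E {r['e_from_slope']:.3f}"
            )
        ax.set_xlabel("log10 expected DNA (ng)")
        ax.set_ylabel("Cq")
        return ax

    def plot_amplification(self, batch: str, target: str, ax=None):
        """Raw traces for one batch-target group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for tr in self.model.traces:
            if tr.batch == batch and tr.target == target:
                ax.plot(np.arange(1, tr.cycles + 1), tr.readings, lw=0.8)
        ax.set_xlabel("cycle")
        ax.set_ylabel("fluorescence")
        ax.set_title(f"{target} {batch}")
        return ax
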