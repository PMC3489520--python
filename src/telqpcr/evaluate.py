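"""Scoring fitted results against a simulated plate's ground truth.

Only meaningful for synthetic plates (real assays have no ledger); used by
the test suite and the acceptance script to quantify estimator recovery:
per-reaction efficiency error, T/S recovery error, and the sensitivity /
false-positive behaviour of the outlier filter.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .model import AssayResults
from .simulate import GroundTruth


def efficiency_recovery(results: AssayResults, truth: GroundTruth,
                        mode: str | None = None) -> dict:
    """Fitted per-reaction E vs the simulator's effective E (usable wells)."""
    mode = mode or results.config.baseline_mode
    fits = results.fits
    sub = fits[
        (fits["baseline_mode"] == mode)
        & fits["usable"]
        & (fits["role"] != "ntc")
    ][["batch", "well", "e"]]
    merged = sub.merge(
        truth.wells[["batch", "well", "true_e"]], on=["batch", "well"]
    ).dropna()
    rel = (merged["e"] - merged["true_e"]) / merged["true_e"]
    return {
        "n": int(len(merged)),
        "mean_fitted_e": float(merged["e"].mean()),
        "mean_true_e": float(merged["true_e"].mean()),
        "mean_rel_err": float(rel.mean()),
        "mean_abs_rel_err": float(rel.abs().mean()),
    }


def ts_recovery(results: AssayResults, truth: GroundTruth,
                method: str | None = None) -> dict:
    """Recovered sample-mean T/S vs true T/S (up to a common scale factor).

    T/S is defined relative to the calibrator, whose true ratio is 1 for the
    pooled standard, so no rescaling should be needed; the fitted/true ratio
    is nevertheless normalized by its median to stay insensitive to the
    calibrator convention of a given method.
    """
    method = method or results.config.primary_method
    tbl = results.ts_tables[method].merge(truth.samples, on="sample")
    tbl = tbl.dropna(subset=["ts", "true_ts"])
    ratio = tbl["ts"] / tbl["true_ts"]
    scale = float(ratio.median())
    rel = tbl["ts"] / (scale * tbl["true_ts"]) - 1.0
    cv = tbl["cv"].dropna()
    return {
        "n": int(len(tbl)),
        "scale": scale,
        "rms_rel_err_pct": float(100.0 * np.sqrt((rel**2).mean())),
        "max_abs_rel_err_pct": float(100.0 * rel.abs().max()),
        "mean_replicate_cv_pct": float(cv.mean()) if len(cv) else math.nan,
    }


def outlier_detection(results: AssayResults, truth: GroundTruth,
                      method: str | None = None) -> dict:
    """Sensitivity to injected Cq-shift outliers and false exclusions.

    A shifted well counts as detected when its replicate is excluded by any
    rule (outside the LDR, Cq-triplicate Grubbs outlier, or T/S-replicate
    Grubbs outlier).  A clean-well false exclusion is any excluded replicate
    whose underlying wells were not shifted.
    """
    method = method or results.config.primary_method
    wells = results.well_tables[method]
    injected = truth.wells[truth.wells["is_outlier"]]
    inj_keys = set(zip(injected["batch"], injected["well"]))

    detected = 0
    false_grubbs = 0
    clean_ldr = 0
    excluded = wells[wells["excluded_well"] | wells["ts_outlier"]]
    for r in excluded.itertuples(index=False):
        keys = {(r.batch, r.well_t), (r.batch, r.well_s)}
        if keys & inj_keys:
            continue
        if r.cq_outlier_t or r.cq_outlier_s or r.ts_outlier:
            false_grubbs += 1
        elif r.out_of_ldr:
            clean_ldr += 1
    for b, w in inj_keys:
        hit = wells[
            (wells["batch"] == b) & ((wells["well_t"] == w) | (wells["well_s"] == w))
        ]
        if len(hit) and bool(
            (hit["excluded_well"] | hit["ts_outlier"]).any()
        ):
            detected += 1
    n_inj = len(inj_keys)
    n_clean = len(wells) - len(
        wells.merge(
            injected[["batch", "well"]].rename(columns={"well": "well_t"}),
            on=["batch", "well_t"],
        )
    )
    return {
        "n_injected": n_inj,
        "n_detected": detected,
        "sensitivity_pct": 100.0 * detected / n_inj if n_inj else math.nan,
        # Grubbs 1%-band calls on replicates whose wells are all clean: the
        # false-exclusion count proper
        "false_grubbs_exclusions": false_grubbs,
        # clean replicates excluded by the linear-dynamic-range rule (samples
        # whose telomere content genuinely sits at the curve's edge)
        "clean_ldr_exclusions": clean_ldr,
        "n_clean_replicates": int(n_clean),
    }
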