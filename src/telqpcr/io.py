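"""Tabular input/output and analysis configuration.

The interchange format is a long (tidy) CSV with one fluorescence reading per
row — columns ``batch, well, role, target, sample, replicate, expected_ng,
cycle, fluorescence`` — plus an optional melt table (``batch, well,
temperature, fluorescence``).  Vendor export dialects are out of scope.
Reports are TSV/JSON with stable column order so identical inputs reproduce
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import ROLES, TARGETS, FluorescenceTrace, MeltCurve
from .qc import QCThresholds

log = logging.getLogger("telqpcr")

PLATE_COLUMNS = [
    "batch", "well", "role", "target", "sample", "replicate",
    "expected_ng", "cycle", "fluorescence",
]
MELT_COLUMNS = ["batch", "well", "temperature", "fluorescence"]


class ValidationError(ValueError):
    """Input table violates the plate schema; message lists offending rows."""


@dataclass
class AnalysisConfig:
    """Pipeline settings: thresholds are fixed across batches once chosen."""

    baseline_mode: str = "strict"  # primary baseline mode ("strict" | "min")
    run_rg_variant: bool = True  # also process with the min-fluorescence baseline
    thresholds: dict[str, float] = field(default_factory=dict)  # target -> Nt
    window_width: int = 5
    window_min: int = 4
    window_max: int = 6
    wol_r2_adjust: float = 0.998
    calibrator: str | None = None  # sample id; None -> middle standard step
    methods: tuple[str, ...] = ("pfaffl_lr", "pfaffl_rg", "ruijter", "ddcq")
    primary_method: str = "pfaffl_lr"
    melt_product_tm: float | None = None  # None -> inferred from standard wells
    qc: QCThresholds = field(default_factory=QCThresholds)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["methods"] = list(self.methods)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisConfig":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text(encoding="utf-8")
        payload = json.loads(text)
        qc = payload.pop("qc", None)
        cfg = cls(**{k: v for k, v in payload.items() if k != "methods"},
                  methods=tuple(payload.get("methods", cls.methods)))
        if qc is not None:
            cfg.qc = QCThresholds(**qc)
        return cfg


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _fail(problems: list[str]) -> None:
    if problems:
        shown = problems[:20]
        more = f" (+{len(problems) - 20} more)" if len(problems) > 20 else ""
        raise ValidationError("; ".join(shown) + more)


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate the long-format plate table."""
    df = pd.read_csv(path)
    problems = []
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {', '.join(missing)}")
    df = df[PLATE_COLUMNS].copy()

    bad_role = df.loc[~df["role"].isin(ROLES)]
    for _, r in bad_role.head(5).iterrows():
        problems.append(f"unknown role {r['role']!r} at {r['batch']}/{r['well']}")
    bad_target = df.loc[~df["target"].isin(TARGETS)]
    for _, r in bad_target.head(5).iterrows():
        problems.append(
            f"unknown target {r['target']!r} at {r['batch']}/{r['well']}"
        )

    fl = pd.to_numeric(df["fluorescence"], errors="coerce")
    for _, r in df.loc[fl.isna()].head(5).iterrows():
        problems.append(
            f"non-numeric fluorescence at {r['batch']}/{r['well']} "
            f"cycle {r['cycle']}"
        )
    df["fluorescence"] = fl

    dup = df.duplicated(subset=["batch", "well", "cycle"], keep=False)
    for _, r in df.loc[dup].drop_duplicates(
        subset=["batch", "well", "cycle"]
    ).head(5).iterrows():
        problems.append(
            f"duplicate reading for {r['batch']}/{r['well']} cycle {r['cycle']}"
        )

    std = df["role"] == "standard"
    bad_std = std & ~(pd.to_numeric(df["expected_ng"], errors="coerce") > 0)
    for _, r in df.loc[bad_std].drop_duplicates(
        subset=["batch", "well"]
    ).head(5).iterrows():
        problems.append(
            f"standard well {r['batch']}/{r['well']} missing expected_ng"
        )

    for (batch, well), grp in df.groupby(["batch", "well"], sort=False):
        cyc = grp["cycle"].to_numpy()
        if not np.array_equal(cyc, np.arange(1, cyc.size + 1)):
            problems.append(
                f"cycles not 1-based consecutive for {batch}/{well}"
            )
    _fail(problems)
    return df


def read_melt_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MELT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing melt columns: {', '.join(missing)}")
    return df[MELT_COLUMNS].copy()


def plate_to_traces(df: pd.DataFrame) -> list[FluorescenceTrace]:
    traces = []
    for (batch, well), grp in df.groupby(["batch", "well"], sort=False):
        grp = grp.sort_values("cycle")
        first = grp.iloc[0]
        expected = first["expected_ng"]
        expected = None if pd.isna(expected) else float(expected)
        traces.append(
            FluorescenceTrace(
                batch=str(batch), well=str(well), role=str(first["role"]),
                target=str(first["target"]), sample=str(first["sample"]),
                replicate=int(first["replicate"]),
                expected_ng=expected if first["role"] == "standard" else None,
                readings=grp["fluorescence"].to_numpy(dtype=float),
            )
        )
    return traces


def melt_to_curves(df: pd.DataFrame) -> list[MeltCurve]:
    curves = []
    for (batch, well), grp in df.groupby(["batch", "well"], sort=False):
        grp = grp.sort_values("temperature")
        curves.append(
            MeltCurve(
                batch=str(batch), well=str(well),
                temperatures=grp["temperature"].to_numpy(dtype=float),
                readings=grp["fluorescence"].to_numpy(dtype=float),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_plate_csv(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False)


def write_reports(results, outdir: str | Path) -> list[Path]:
    """Write the deterministic report bundle for a fitted assay.

    Per-well fits TSV, standard-curve TSV, one T/S TSV per method, a T/S
    summary TSV, QC metrics JSON and the scorecard JSON.  Missing pieces are
    skipped with a warning; reruns on identical inputs are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _tsv(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=False)
        written.append(p)

    if results.fits is not None:
        _tsv(results.fits.sort_values(
            ["baseline_mode", "batch", "target", "well"]
        ), "fits.tsv")
    if results.standard_curves is not None:
        _tsv(results.standard_curves, "standard_curves.tsv")
    for method, table in sorted(results.ts_tables.items()):
        _tsv(table, f"ts_{method}.tsv")
    if results.ts_summary is not None:
        _tsv(results.ts_summary, "ts_summary.tsv")
    if results.qc_metrics is not None:
        p = outdir / "qc_metrics.json"
        p.write_text(
            json.dumps(results.qc_metrics, indent=2, sort_keys=True,
                       default=_jsonable) + "\n",
            encoding="utf-8",
        )
        written.append(p)
    if results.scorecard is not None:
        p = outdir / "scorecard.json"
        p.write_text(
            json.dumps(results.scorecard.to_dict(), indent=2, sort_keys=True,
                       default=_jsonable) + "\n",
            encoding="utf-8",
        )
        written.append(p)
    else:
        log.warning("no scorecard available; writing partial bundle")
    return written


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
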