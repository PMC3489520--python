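"""Seeded synthetic qPCR plates with a ground-truth ledger.

The generator emulates the plate design used for relative telomere length
estimation: a serial dilution series of pooled standard DNA (default
72 -> 4.5 ng at 2-fold, five steps) run in triplicate for both the telomere
and a single-copy reference target, no-template controls (NTC) in triplicate,
and a set of "unknown" samples with a known true T/S ratio, across several
batches.  Every simulated well is recorded in a ground-truth table so each
downstream estimator can be scored against what it should recover.

Amplification follows a logistic-depletion recurrence with a sharpness
exponent h (``depletion_hill``):

    A(c+1) = A(c) * (1 + (E - 1) * (1 - (A(c)/plateau)**h)),
    F(c)   = baseline + A(c) + noise.

h = 1 is the textbook logistic; the default h = 4 keeps growth log-linear
until shortly below the plateau, as real SYBR-green chemistry does (reagent
depletion is late-onset), so per-reaction efficiency fits are unbiased over
the observable window.  Loss of effective efficiency at high template
amounts is modelled separately as a linear reduction of E per ng of input.  Reference reactions sit
15-20 Cq above telomere reactions, as typical for single-copy genes
normalizing an abundant repeat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import FluorescenceTrace, InvalidParameterError, MeltCurve

_KIND_STANDARD, _KIND_NTC, _KIND_UNKNOWN = 1, 2, 3
_TARGET_CODE = {"telomere": 1, "reference": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic assay.

    Defaults reproduce a clean, well-optimized assay: a 72->4.5 ng 2-fold
    five-step dilution series in triplicate over four batches, near-perfect
    telomere efficiency, reference efficiency 1.9, read noise at 1% of the
    plateau fluorescence and a per-well Cq jitter of 0.12 cycles (the
    triplicate Cq scatter of a good assay).
    """

    seed: int = 0
    cycles: int = 40
    dilution_top: float = 72.0
    dilution_fold: float = 2.0
    dilution_steps: int = 5
    replicates: int = 3
    batches: int = 4
    true_E_telomere: float = 2.0
    true_E_reference: float = 1.9
    efficiency_decay: float = 0.0  # E lost per ng template
    efficiency_decay_reference: float | None = None  # falls back to efficiency_decay
    batch_e_sd: float = 0.0  # SD of per-batch efficiency offsets
    baseline_level: float = 10.0
    baseline_sd: float = 1.0
    noise_sd: float = 1.0
    plateau: float = 100.0
    depletion_hill: float = 4.0  # sharpness of reagent depletion; 1 = logistic
    n_unknowns: int = 60
    unknown_ng: float = 20.0
    true_ts_range: tuple[float, float] = (0.45, 2.9)
    cq_sd: float = 0.08  # independent per-well Cq jitter, cycles
    # template-amount jitter shared by both targets of a replicate (2-fold
    # cycles): in a multiplex reaction T and S sit in one tube, so pipetting
    # error is common to both and largely cancels in the T/S ratio; the
    # per-target Cq SD is sqrt(cq_sd^2 + (shared in that target's cycles)^2)
    # ~ 0.12 with the defaults
    cq_shared_sd: float = 0.09
    tel_n0_per_ng: float = 1.2e-5  # fluorescence-equivalent N0 per ng, telomere
    ref_cq_offset: float = 17.0  # reference Cq lag behind telomere, cycles
    ntc_dimer: bool = False
    dimer_cq: float = 28.0
    melt_peak_product: float = 80.0
    melt_peak_dimer: float = 87.0
    melt_min: float = 72.0
    melt_max: float = 95.0
    melt_step: float = 0.5
    melt_noise_sd: float = 0.002
    outlier_spec: tuple[tuple[str, str, float], ...] = ()  # (batch, well, Cq shift)

    def validate(self) -> None:
        if self.cycles < 10:
            raise InvalidParameterError("cycles must be >= 10")
        if not self.dilution_fold > 1:
            raise InvalidParameterError("dilution_fold must exceed 1")
        if self.dilution_steps < 3:
            raise InvalidParameterError("dilution_steps must be >= 3")
        if self.replicates < 1 or self.batches < 1:
            raise InvalidParameterError("replicates and batches must be >= 1")
        for name in ("true_E_telomere", "true_E_reference"):
            e = getattr(self, name)
            if not (1.0 < e <= 2.05):
                raise InvalidParameterError(f"{name} must be in (1, 2.05]")
        for name in (
            "efficiency_decay",
            "batch_e_sd",
            "baseline_sd",
            "noise_sd",
            "cq_sd",
            "cq_shared_sd",
            "melt_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not self.plateau > 0:
            raise InvalidParameterError("plateau must be positive")
        if not self.depletion_hill >= 1:
            raise InvalidParameterError("depletion_hill must be >= 1")
        if not self.dilution_top > 0 or not self.unknown_ng > 0:
            raise InvalidParameterError("DNA amounts must be positive")
        if not self.true_ts_range[0] > 0 or not (
            self.true_ts_range[1] >= self.true_ts_range[0]
        ):
            raise InvalidParameterError("true_ts_range must be positive and ordered")

    @property
    def step_amounts(self) -> tuple[float, ...]:
        return tuple(
            self.dilution_top / self.dilution_fold**k
            for k in range(self.dilution_steps)
        )

    def decay_for(self, target: str) -> float:
        if target == "reference" and self.efficiency_decay_reference is not None:
            return self.efficiency_decay_reference
        return self.efficiency_decay

    def n0_per_ng(self, target: str) -> float:
        if target == "telomere":
            return self.tel_n0_per_ng
        return self.tel_n0_per_ng * self.true_E_reference ** (-self.ref_cq_offset)


def clean_assay_config(**overrides) -> SimulationConfig:
    """A well-optimized multiplex-style assay: the defaults unchanged.

    High telomere efficiency, reference at 1.9, no template-dependent
    efficiency loss, batch-stable efficiencies.
    """
    return SimulationConfig(**overrides)


def decaying_efficiency_config(**overrides) -> SimulationConfig:
    """An assay whose efficiency falls with template amount.

    The decay rates are sized to lose roughly eight efficiency percentage
    points across a 72 -> 4.5 ng series (stronger for the telomere target),
    which bends the top of the standard curve and makes T/S drift across
    dilution steps.
    """
    params = dict(
        efficiency_decay=0.0012,  # E per ng: ~0.08 across the 67.5 ng span
        efficiency_decay_reference=0.0004,
        noise_sd=0.25,  # quieter optics, so the per-well E trend is resolvable
        cq_sd=0.33,  # poorer replicate Cq precision ...
        cq_shared_sd=0.0,  # ... fully independent: T and S run in singleplex
    )
    params.update(overrides)
    return SimulationConfig(**params)


def inhibited_reference_config(**overrides) -> SimulationConfig:
    """A poorly multiplexed assay: low, batch-variable reference efficiency.

    Mimics primer competition suppressing the reference reaction (low E,
    unstable across batches) with primer-dimer signal in the reference NTCs.
    """
    params = dict(
        true_E_reference=1.45,
        batch_e_sd=0.08,
        ntc_dimer=True,
        dimer_cq=22.0,  # dimers amplify efficiently: NTC crosses well before
        # the sluggish low-E reference standards (the overlap signature)
        ref_cq_offset=6.0,  # keep the slow low-E reference inside 40 cycles
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class GroundTruth:
    """Per-well and per-sample truth for a simulated plate."""

    wells: pd.DataFrame  # one row per well
    samples: pd.DataFrame  # sample, true_ts


@dataclass
class SimulatedPlate:
    traces: list[FluorescenceTrace]
    melts: list[MeltCurve]
    truth: GroundTruth
    config: SimulationConfig

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Long-format plate and melt tables (one reading per row)."""
        plate_rows = []
        for tr in self.traces:
            for c, f in enumerate(tr.readings, start=1):
                plate_rows.append(
                    (
                        tr.batch,
                        tr.well,
                        tr.role,
                        tr.target,
                        tr.sample,
                        tr.replicate,
                        tr.expected_ng,
                        c,
                        f,
                    )
                )
        plate = pd.DataFrame(
            plate_rows,
            columns=[
                "batch",
                "well",
                "role",
                "target",
                "sample",
                "replicate",
                "expected_ng",
                "cycle",
                "fluorescence",
            ],
        )
        melt_rows = []
        for mc in self.melts:
            for t, f in zip(mc.temperatures, mc.readings):
                melt_rows.append((mc.batch, mc.well, t, f))
        melt = pd.DataFrame(
            melt_rows, columns=["batch", "well", "temperature", "fluorescence"]
        )
        return plate, melt


# ---------------------------------------------------------------------------
# RNG plumbing: one top-level seed, deterministic per-well substreams keyed by
# the well's semantic identity so changing e.g. n_unknowns does not reshuffle
# the noise of unrelated wells.
# ---------------------------------------------------------------------------


def _well_rng(config: SimulationConfig, batch_i: int, kind: int, tgt: int,
              sample_key: int, replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        [int(config.seed) & 0x7FFFFFFF, batch_i, kind, tgt, sample_key, replicate]
    )
    return np.random.default_rng(ss)


def _aux_rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0xA0A0, stream])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# amplification
# ---------------------------------------------------------------------------


def _amplify(
    n0: float,
    efficiency: float,
    config: SimulationConfig,
    baseline: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    a = n0
    plateau = config.plateau
    h = config.depletion_hill
    out = np.empty(config.cycles, dtype=float)
    for c in range(config.cycles):
        if a > 0:
            depletion = max(0.0, 1.0 - (a / plateau) ** h)
            a = min(a * (1.0 + (efficiency - 1.0) * depletion), plateau)
        out[c] = baseline + a
    if rng is not None and config.noise_sd > 0:
        out += rng.normal(0.0, config.noise_sd, size=config.cycles)
    return out


def simulate_trace(
    n0: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    efficiency: float | None = None,
    baseline: float | None = None,
    **meta,
) -> FluorescenceTrace:
    """Simulate a single amplification trace from starting signal ``n0``.

    In the pre-threshold phase the corrected signal grows geometrically at
    rate E; it saturates below ``baseline + plateau`` (up to noise).
    """
    config.validate()
    if not n0 > 0:
        raise InvalidParameterError("n0 must be positive")
    e = config.true_E_telomere if efficiency is None else efficiency
    if not (1.0 < e <= 2.05):
        raise InvalidParameterError("efficiency must be in (1, 2.05]")
    b = config.baseline_level if baseline is None else baseline
    readings = _amplify(n0, e, config, b, rng)
    defaults = dict(
        batch="B1", well="W001", role="unknown", target="telomere",
        sample="sim", replicate=1, expected_ng=None,
    )
    defaults.update(meta)
    return FluorescenceTrace(readings=readings, **defaults)


def simulate_melt_curve(
    peaks: Sequence[tuple[float, float]],
    rng: np.random.Generator | None = None,
    t_min: float = 72.0,
    t_max: float = 95.0,
    step: float = 0.5,
    noise_sd: float = 0.0,
    width: float = 0.4,
    batch: str = "B1",
    well: str = "W001",
) -> MeltCurve:
    """Dissociation curve whose -dF/dT peaks sit at the requested melting points.

    Each (Tm, height) pair contributes a logistic drop of the given height
    centred at Tm; the negative derivative then has a local maximum at
    Tm +- the scan step.
    """
    if not peaks:
        raise InvalidParameterError("at least one melt peak required")
    for tm, h in peaks:
        if not (t_min <= tm <= t_max):
            raise InvalidParameterError(f"melt peak {tm} outside scan range")
        if not h > 0:
            raise InvalidParameterError("peak height must be positive")
    temps = np.arange(t_min, t_max + step / 2, step)
    f = np.zeros_like(temps)
    for tm, h in peaks:
        f += h / (1.0 + np.exp((temps - tm) / width))
    if rng is not None and noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=temps.size)
    return MeltCurve(batch=batch, well=well, temperatures=temps, readings=f)


# ---------------------------------------------------------------------------
# plate assembly
# ---------------------------------------------------------------------------


def plate_layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic well layout (no randomness): one row per well.

    Useful for addressing wells in ``outlier_spec`` before simulating.
    """
    config.validate()
    rows = []
    for bi in range(config.batches):
        batch = f"B{bi + 1}"
        widx = 0
        for target in ("telomere", "reference"):
            for si, amount in enumerate(config.step_amounts):
                for rep in range(1, config.replicates + 1):
                    widx += 1
                    rows.append(
                        (batch, f"W{widx:03d}", "standard", target,
                         f"std_{amount:g}", rep, amount, _KIND_STANDARD, si)
                    )
            for rep in range(1, 4):
                widx += 1
                rows.append(
                    (batch, f"W{widx:03d}", "ntc", target, "ntc", rep,
                     math.nan, _KIND_NTC, 9000)
                )
            for ui in range(config.n_unknowns):
                for rep in range(1, config.replicates + 1):
                    widx += 1
                    rows.append(
                        (batch, f"W{widx:03d}", "unknown", target,
                         f"u{ui:02d}", rep, config.unknown_ng, _KIND_UNKNOWN, ui)
                    )
    return pd.DataFrame(
        rows,
        columns=["batch", "well", "role", "target", "sample", "replicate",
                 "amount_ng", "kind", "sample_key"],
    )


def simulate_plate(config: SimulationConfig) -> SimulatedPlate:
    """Simulate all batches of an assay; returns traces, melt curves and truth."""
    config.validate()
    layout = plate_layout(config)

    shift_map = {(b, w): s for b, w, s in config.outlier_spec}
    known = set(zip(layout["batch"], layout["well"]))
    for key in shift_map:
        if key not in known:
            raise InvalidParameterError(f"outlier_spec addresses unknown well {key}")

    ts_rng = _aux_rng(config, 1)
    true_ts = ts_rng.uniform(*config.true_ts_range, size=config.n_unknowns)
    be_rng = _aux_rng(config, 2)
    batch_offsets = (
        be_rng.normal(0.0, config.batch_e_sd, size=(config.batches, 2))
        if config.batch_e_sd > 0
        else np.zeros((config.batches, 2))
    )

    traces: list[FluorescenceTrace] = []
    melts: list[MeltCurve] = []
    truth_rows = []

    for row in layout.itertuples(index=False):
        bi = int(row.batch[1:]) - 1
        tgt_code = _TARGET_CODE[row.target]
        rng = _well_rng(config, bi, int(row.kind), tgt_code,
                        int(row.sample_key), int(row.replicate))
        base_e = (
            config.true_E_telomere if row.target == "telomere"
            else config.true_E_reference
        )
        e_eff = base_e + batch_offsets[bi, tgt_code - 1]

        dimer_here = (
            row.role == "ntc" and config.ntc_dimer and row.target == "reference"
        )
        if row.role == "ntc":
            if dimer_here:
                e_ntc = min(max(1.01, config.true_E_reference), 2.05)
                n0 = 1.0 * e_ntc ** (-config.dimer_cq)
                e_eff = e_ntc
            else:
                n0 = 0.0
            amount = math.nan
            ts = math.nan
        else:
            amount = float(row.amount_ng)
            e_eff = float(np.clip(e_eff - config.decay_for(row.target) * amount,
                                  1.01, 2.05))
            scale = config.n0_per_ng(row.target)
            ts = 1.0 if row.role == "standard" else float(true_ts[row.sample_key])
            n0 = amount * scale * (ts if row.target == "telomere" else 1.0)
            if config.cq_sd > 0:
                n0 *= e_eff ** (-rng.normal(0.0, config.cq_sd))
            if config.cq_shared_sd > 0:
                shared_rng = _well_rng(
                    config, bi, int(row.kind), 0, int(row.sample_key),
                    int(row.replicate),
                )
                n0 *= 2.0 ** (-shared_rng.normal(0.0, config.cq_shared_sd))

        shift = shift_map.get((row.batch, row.well), 0.0)
        if shift and n0 > 0:
            n0 *= e_eff ** (-shift)

        baseline = max(0.1, rng.normal(config.baseline_level, config.baseline_sd))
        readings = _amplify(n0, e_eff if n0 > 0 else 2.0, config, baseline, rng)
        traces.append(
            FluorescenceTrace(
                batch=row.batch, well=row.well, role=row.role, target=row.target,
                sample=row.sample, replicate=int(row.replicate),
                expected_ng=amount if row.role == "standard" else None,
                readings=readings,
            )
        )

        if row.role in ("standard", "ntc"):
            if row.role == "standard":
                peaks = [(config.melt_peak_product, 1.0)]
            elif dimer_here:
                peaks = [(config.melt_peak_dimer, 0.4)]
            else:
                peaks = None
            if peaks is None:
                temps = np.arange(
                    config.melt_min, config.melt_max + config.melt_step / 2,
                    config.melt_step,
                )
                f = (
                    rng.normal(0.0, config.melt_noise_sd, size=temps.size)
                    if config.melt_noise_sd > 0
                    else np.zeros_like(temps)
                )
                melts.append(MeltCurve(row.batch, row.well, temps, f))
            else:
                melts.append(
                    simulate_melt_curve(
                        peaks, rng, config.melt_min, config.melt_max,
                        config.melt_step, config.melt_noise_sd,
                        batch=row.batch, well=row.well,
                    )
                )

        truth_rows.append(
            (
                row.batch, row.well, row.role, row.target, row.sample,
                int(row.replicate), amount, n0,
                e_eff if n0 > 0 else math.nan, ts, shift, bool(shift),
            )
        )

    wells = pd.DataFrame(
        truth_rows,
        columns=["batch", "well", "role", "target", "sample", "replicate",
                 "amount_ng", "true_n0", "true_e", "true_ts", "cq_shift",
                 "is_outlier"],
    )
    samples = pd.DataFrame(
        {"sample": [f"u{i:02d}" for i in range(config.n_unknowns)],
         "true_ts": true_ts}
    )
    return SimulatedPlate(traces, melts, GroundTruth(wells, samples), config)
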