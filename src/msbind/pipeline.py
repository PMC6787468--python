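"""Screen orchestration: reporter quantification -> sublibrary activity ->
hit identification -> reduced-sublibrary bookkeeping.

The workflow mirrors a pooled-library competitive binding screen read out by
LC-ESI-MS/MS.  Stage 1 turns every reporter-ligand MRM readout into a
concentration via the per-experiment calibration line.  Stage 2 computes, per
sublibrary, the specific reporter binding remaining relative to a shared
no-library control and applies the activity (< 50%) and anomaly (> 150%)
criteria.  Stage 3 runs, only for sublibraries that met either criterion, the
one-sided total-vs-nonspecific t-test on every component's normalised areas
and, where a relative response factor is known, estimates the specifically
bound concentration.  Stage 4 derives the reduced sublibraries (parent minus
hits) and, when measurements for them are present, assesses whether further
hits are likely still hiding in the pool.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import hitcalling, quant
from .errors import InputError, MissingConditionError, SchemaError
from .hitcalling import ActivityResult, TripletSummary
from .quant import ResponseFactor

__all__ = [
    "AssayConfig",
    "Sublibrary",
    "HitRecord",
    "ReducedResult",
    "ScreenReport",
    "run_screen",
    "build_reduced_sublibrary",
    "quantify_reporter",
]


@dataclass(frozen=True)
class AssayConfig:
    """Assay parameters shared by the model, the pipeline and the simulator.

    Defaults describe the GAT1 screen this package models: reporter NO711 at
    10 nM (Kd 23.6 nM, koff 1.5e-3 s^-1), target ~3 nM (0.125 Kd, low enough
    to limit reporter depletion yet high enough for component detection),
    library components pooled at 1 uM each, nonspecific binding defined by a
    100 mM GABA block, a deuterated internal standard at 1 nM in the LC
    sample, and a 430/200 uL elution dilution (factor 2.15).
    """

    reporter_conc: float = 10.0  # nM
    reporter_kd: float = 23.6  # nM
    reporter_koff: float = 1.5e-3  # s^-1
    target_conc: float = 3.0  # nM
    component_conc: float = 1000.0  # nM
    replicates: int = 3
    activity_threshold_pct: float = 50.0
    anomaly_threshold_pct: float = 150.0
    confidence_level: float = 97.5  # one-sided, percent
    is_conc_lcms: float = 1.0  # nM
    dilution_factor: float = 2.15  # final LC volume / filtered aliquot
    blocker_conc: float = 1e8  # nM (100 mM GABA)
    blocker_ki: float = 1e4  # nM
    wash_time: float = 30.0  # s, effective first-order wash interval
    reporter_id: str = "NO711"
    is_id: str = "d10-NO711"

    def __post_init__(self):
        positive = [
            "reporter_conc", "reporter_kd", "reporter_koff", "target_conc",
            "component_conc", "activity_threshold_pct", "anomaly_threshold_pct",
            "confidence_level", "is_conc_lcms", "dilution_factor",
            "blocker_conc", "blocker_ki",
        ]
        for name in positive:
            if not (getattr(self, name) > 0):
                raise InputError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.replicates < 2:
            raise InputError(f"replicates must be >= 2, got {self.replicates}")
        if self.wash_time < 0:
            raise InputError(f"wash_time must be >= 0, got {self.wash_time}")
        if not (self.activity_threshold_pct < self.anomaly_threshold_pct):
            raise InputError("activity threshold must lie below anomaly threshold")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class Sublibrary:
    """An ordered pool of compounds incubated together in one experiment."""

    sublibrary_id: str
    components: tuple[str, ...]
    component_conc: Mapping[str, float] | None = None

    def __post_init__(self):
        if len(self.components) < 1:
            raise InputError(f"sublibrary {self.sublibrary_id!r} is empty")
        if len(set(self.components)) != len(self.components):
            raise InputError(
                f"sublibrary {self.sublibrary_id!r} has duplicate components"
            )

    def conc_of(self, compound_id: str, default: float) -> float:
        if self.component_conc and compound_id in self.component_conc:
            return self.component_conc[compound_id]
        return default


@dataclass(frozen=True)
class HitRecord:
    """Per-component hit-calling outcome within one active sublibrary."""

    sublibrary_id: str
    analyte_id: str
    delta: float
    t_stat: float
    df: int
    critical_value: float
    significant: bool
    conc_lc_nM: float | None
    conc_sample_nM: float | None
    estimable: bool
    floored: bool


@dataclass(frozen=True)
class ReducedResult:
    """A reduced sublibrary (parent minus hits) and, if measured, its activity."""

    sublibrary_id: str
    parent_id: str
    components: tuple[str, ...]
    activity: ActivityResult | None
    further_hits_likely: bool | None


@dataclass(frozen=True)
class ScreenReport:
    """Full screen outcome; serialises deterministically via :meth:`to_dict`."""

    config_hash: str
    activity: tuple[ActivityResult, ...]
    hits: tuple[HitRecord, ...]
    reduced: tuple[ReducedResult, ...]
    not_measured: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict:
        def clean(value):
            if isinstance(value, float) and not math.isfinite(value):
                return None if math.isnan(value) else ("inf" if value > 0 else "-inf")
            return value

        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "activity": [
                {k: clean(v) for k, v in dataclasses.asdict(a).items()}
                for a in self.activity
            ],
            "hits": [
                {k: clean(v) for k, v in dataclasses.asdict(h).items()}
                for h in self.hits
            ],
            "reduced": [
                {
                    "sublibrary_id": r.sublibrary_id,
                    "parent_id": r.parent_id,
                    "components": list(r.components),
                    "activity": (
                        None
                        if r.activity is None
                        else {k: clean(v) for k, v in dataclasses.asdict(r.activity).items()}
                    ),
                    "further_hits_likely": r.further_hits_likely,
                }
                for r in self.reduced
            ],
            "not_measured": {k: list(v) for k, v in sorted(self.not_measured.items())},
        }

    def activity_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(a) for a in self.activity])

    def hits_frame(self) -> pd.DataFrame:
        cols = [f.name for f in dataclasses.fields(HitRecord)]
        return pd.DataFrame([dataclasses.asdict(h) for h in self.hits], columns=cols)

    def hit_ids(self, sublibrary_id: str) -> list[str]:
        return [
            h.analyte_id
            for h in self.hits
            if h.sublibrary_id == sublibrary_id and h.significant
        ]


def build_reduced_sublibrary(parent: Sublibrary, hits: Sequence[str]) -> Sublibrary:
    """Parent sublibrary with its hits removed, order preserved, id suffixed."""
    unknown = [h for h in hits if h not in parent.components]
    if unknown:
        raise InputError(
            f"hits {unknown} not in sublibrary {parent.sublibrary_id!r}"
        )
    hit_set = set(hits)
    return Sublibrary(
        sublibrary_id=parent.sublibrary_id + "-reduced",
        components=tuple(c for c in parent.components if c not in hit_set),
        component_conc=parent.component_conc,
    )


def _reporter_calibrations(measurements: pd.DataFrame, config: AssayConfig):
    """Per-plate calibration curves from standard rows; global fallback."""
    std = measurements[
        (measurements["condition"] == "standard")
        & (measurements["analyte_id"] == config.reporter_id)
    ]
    if len(std) == 0:
        raise SchemaError(
            f"no calibration standards for reporter {config.reporter_id!r}"
        )

    def fit(rows):
        pairs = [
            (float(r.standard_conc_nM), r.peak_area / r.is_peak_area)
            for r in rows.itertuples()
        ]
        return quant.fit_calibration(pairs)

    curves = {plate: fit(grp) for plate, grp in std.groupby("plate_id")}
    curves[None] = fit(std)
    return curves


def quantify_reporter(
    measurements: pd.DataFrame, config: AssayConfig
) -> pd.DataFrame:
    """Stage 1: reporter concentration per binding sample.

    Returns the reporter rows (conditions other than ``standard``) with
    ``normalized_area``, ``conc_lc_nM`` and ``conc_sample_nM`` columns added;
    the sample-scale value multiplies the LC concentration by the elution
    dilution factor.
    """
    curves = _reporter_calibrations(measurements, config)
    rep = measurements[
        (measurements["analyte_id"] == config.reporter_id)
        & (measurements["condition"] != "standard")
    ].copy()
    if len(rep) == 0:
        raise SchemaError(f"no reporter rows for analyte {config.reporter_id!r}")
    rep["normalized_area"] = rep["peak_area"] / rep["is_peak_area"]
    conc = [
        quant.quantify(
            curves.get(r.plate_id, curves[None]), r.normalized_area,
            warn_extrapolation=False,
        )
        for r in rep.itertuples()
    ]
    rep["conc_lc_nM"] = conc
    rep["conc_sample_nM"] = rep["conc_lc_nM"] * config.dilution_factor
    return rep


def _replicate_concs(frame: pd.DataFrame) -> np.ndarray:
    return frame.sort_values("replicate")["conc_sample_nM"].to_numpy()


def _control_arrays(rep: pd.DataFrame, plate_id) -> tuple[np.ndarray, np.ndarray]:
    """Control total and control nonspecific reporter levels for one plate.

    An explicit control_nonspecific triplicate wins; otherwise the plate's
    pooled nonspecific reporter levels stand in for the control's nonspecific
    correction.
    """
    plate = rep[rep["plate_id"] == plate_id]
    ctrl_total = plate[plate["condition"] == "control_total"]
    if len(ctrl_total) == 0:
        raise MissingConditionError(str(plate_id), "control_total")
    ctrl_ns = plate[plate["condition"] == "control_nonspecific"]
    if len(ctrl_ns) > 0:
        ns_vals = ctrl_ns["conc_sample_nM"].to_numpy()
    else:
        pooled = plate[plate["condition"] == "nonspecific"]
        if len(pooled) == 0:
            raise MissingConditionError(str(plate_id), "nonspecific")
        ns_vals = pooled["conc_sample_nM"].to_numpy()
    return ctrl_total["conc_sample_nM"].to_numpy(), ns_vals


def run_screen(
    measurements: pd.DataFrame,
    library: Sequence[Sublibrary],
    config: AssayConfig,
    rrfs: Mapping[str, ResponseFactor | float] | None = None,
    seed: int | None = None,
) -> ScreenReport:
    """Run the full screen on a validated measurement table.

    ``library`` lists the sublibraries as assayed (ids ending in ``-reduced``
    are treated as verification pools of their parent, not screened
    themselves).  ``rrfs`` maps compound ids to relative response factors for
    the specific-binding concentration estimates; compounds without one get a
    delta-only hit record.
    """
    from .io import validate_measurements

    validate_measurements(measurements)
    rrfs = dict(rrfs or {})
    known_analytes = {config.reporter_id} | {
        c for sl in library for c in sl.components
    }
    unknown = set(measurements["analyte_id"].unique()) - known_analytes
    if unknown:
        raise SchemaError(f"unknown analyte ids in measurements: {sorted(unknown)}")

    rep = quantify_reporter(measurements, config)
    primary = [sl for sl in library if not sl.sublibrary_id.endswith("-reduced")]
    measured_ids = set(measurements["sublibrary_id"].unique())

    def assess(sl_id: str) -> ActivityResult:
        rows = rep[rep["sublibrary_id"] == sl_id]
        total = rows[rows["condition"] == "total"]
        if len(total) == 0:
            raise MissingConditionError(sl_id, "total")
        ns = rows[rows["condition"] == "nonspecific"]
        if len(ns) == 0:
            raise MissingConditionError(sl_id, "nonspecific")
        plate_id = total["plate_id"].iloc[0]
        ctrl_total, ctrl_ns = _control_arrays(rep, plate_id)
        pct, sd = hitcalling.remaining_specific_binding(
            _replicate_concs(total), _replicate_concs(ns), ctrl_total, ctrl_ns
        )
        return hitcalling.classify_activity(
            pct, config, sublibrary_id=sl_id, remaining_sd=sd
        )

    activity = tuple(assess(sl.sublibrary_id) for sl in primary)
    gated = {
        a.sublibrary_id for a in activity if a.active or a.anomaly
    }

    hits: list[HitRecord] = []
    not_measured: dict[str, tuple[str, ...]] = {}
    for sl in primary:
        if sl.sublibrary_id not in gated:
            continue
        skipped = []
        for comp in sl.components:
            rows = measurements[
                (measurements["sublibrary_id"] == sl.sublibrary_id)
                & (measurements["analyte_id"] == comp)
            ]
            tot = rows[rows["condition"] == "total"]
            ns = rows[rows["condition"] == "nonspecific"]
            if len(tot) == 0 and len(ns) == 0:
                skipped.append(comp)  # not detectable by MRM; no readout rows
                continue
            if len(tot) < 2 or len(ns) < 2:
                raise MissingConditionError(
                    sl.sublibrary_id, f"total/nonspecific for analyte {comp!r}"
                )
            na_tot = (tot["peak_area"] / tot["is_peak_area"]).to_numpy()
            na_ns = (ns["peak_area"] / ns["is_peak_area"]).to_numpy()
            call = hitcalling.one_sided_t(
                TripletSummary.from_values(comp, "total", na_tot),
                TripletSummary.from_values(comp, "nonspecific", na_ns),
                config.confidence_level,
            )
            rf = rrfs.get(comp)
            if isinstance(rf, (int, float)):
                rf = ResponseFactor(comp, float(rf))
            est = quant.bound_conc_estimate(
                call.delta, rf, config.is_conc_lcms, config.dilution_factor
            )
            hits.append(
                HitRecord(
                    sublibrary_id=sl.sublibrary_id,
                    analyte_id=comp,
                    delta=call.delta,
                    t_stat=call.t_stat,
                    df=call.df,
                    critical_value=call.critical_value,
                    significant=call.significant,
                    conc_lc_nM=est.conc_lc_nM,
                    conc_sample_nM=est.conc_sample_nM,
                    estimable=est.estimable,
                    floored=est.floored,
                )
            )
        if skipped:
            not_measured[sl.sublibrary_id] = tuple(skipped)

    reduced: list[ReducedResult] = []
    for sl in primary:
        if sl.sublibrary_id not in gated:
            continue
        hit_ids = [
            h.analyte_id
            for h in hits
            if h.sublibrary_id == sl.sublibrary_id and h.significant
        ]
        red = build_reduced_sublibrary(sl, hit_ids)
        red_activity = None
        further = None
        if red.sublibrary_id in measured_ids:
            red_activity = assess(red.sublibrary_id)
            further = red_activity.remaining_pct < config.activity_threshold_pct
        reduced.append(
            ReducedResult(
                sublibrary_id=red.sublibrary_id,
                parent_id=sl.sublibrary_id,
                components=red.components,
                activity=red_activity,
                further_hits_likely=further,
            )
        )

    return ScreenReport(
        config_hash=config.config_hash(),
        activity=activity,
        hits=tuple(hits),
        reduced=tuple(reduced),
        not_measured=not_measured,
        seed=seed,
    )
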