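"""Synthetic binding-experiment generator.

Emulates the generative structure the analysis assumes, end to end:

1. competitive single-site equilibrium of the reporter, every binding library
   component and — in the nonspecific condition — a blocking ligand in vast
   excess, all with explicit target and ligand depletion;
2. first-order dissociation losses while the filter is washed (per-ligand
   koff, derived from the ligand's Ki and a default association rate when no
   measured koff is available);
3. a linear, non-saturable, blocker-insensitive nonspecific carry-over of
   every compound (fraction of its total concentration retained after wash) —
   exactly the property the total-minus-nonspecific subtraction assumes;
4. dilution of the filtered aliquot into the final LC sample (inverse of the
   analysis dilution factor);
5. multiplicative log-normal LC-MS measurement noise on analyte and
   internal-standard peak areas alike, independent per readout, all drawn
   from a caller-supplied seed.

Ground truth (true Ki/koff/RRF/nonspecific level per compound, true bound
concentrations before and after wash per sample) is recorded alongside so
tests can invert the simulation exactly at zero noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .equilibrium import LigandSite, koff_from_kd, solve_equilibrium
from .errors import InputError
from .hitcalling import TripletSummary
from .pipeline import AssayConfig, Sublibrary

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CompoundTruth",
    "generate_library",
    "simulate_screen",
    "make_fixture",
]

#: peak-area counts emitted per nM of analyte at RRF 1 (arbitrary instrument scale)
AREA_PER_NM = 5.0e4

_BLOCKER_ID = "__blocker__"


@dataclass(frozen=True)
class SimulationConfig:
    """Noise and nuisance-process parameters of the simulated experiment.

    ``noise_cv`` is the fractional coefficient of variation of the
    multiplicative log-normal measurement noise (sigma = ln(1 + cv)).
    ``nonspecific_coeff`` is the fraction of a compound's total concentration
    retained nonspecifically after wash (override per compound via
    ``nonspecific_overrides``); ``ns_wash_retention`` scales how much of that
    survives washing.  ``kon_default`` supplies koff = kon * Ki for compounds
    without a measured dissociation rate.
    """

    seed: int
    noise_cv: float = 0.05
    nonspecific_coeff: float = 1e-4
    nonspecific_overrides: Mapping[str, float] = field(default_factory=dict)
    ns_wash_retention: float = 1.0
    kon_default: float = 6.4e4  # M^-1 s^-1
    response_factor_default: float = 1.0
    calibration_levels: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0)

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise InputError("seed is mandatory and must be an integer")
        if self.noise_cv < 0:
            raise InputError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.nonspecific_coeff < 0 or any(
            v < 0 for v in self.nonspecific_overrides.values()
        ):
            raise InputError("nonspecific coefficients must be >= 0")
        if not (self.ns_wash_retention >= 0):
            raise InputError("ns_wash_retention must be >= 0")
        if not (self.kon_default > 0):
            raise InputError("kon_default must be > 0")

    @property
    def sigma(self) -> float:
        return math.log1p(self.noise_cv)


@dataclass
class CompoundTruth:
    """True parameters of one simulated compound (ki None for non-binders)."""

    ki_nM: float | None
    koff_s: float | None
    rrf: float
    nonspecific_level_nM: float  # retained nonspecifically, binding-sample scale
    koff_assumed: bool = True  # True when koff came from the kon-default convention


@dataclass
class GroundTruth:
    """Everything needed to recompute expected measurements with zero noise."""

    compounds: dict[str, CompoundTruth] = field(default_factory=dict)
    samples: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "compounds": {
                cid: dataclasses.asdict(ct) for cid, ct in self.compounds.items()
            },
            "samples": self.samples,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def generate_library(
    n_compounds: int,
    sublibrary_size: int,
    planted_hits: Sequence[tuple[int, float]],
    seed: int,
    component_conc: float = 1000.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Build a pooled screening library with planted inhibitors.

    Compounds are split in file order into sublibraries of ``sublibrary_size``
    (which must divide ``n_compounds``).  ``planted_hits`` assigns a true Ki
    (nM) to chosen compound indices; every other compound is a non-binder.
    RRFs are drawn log-uniformly on [0.05, 5], covering the wide spread of
    electrospray response across a diverse small-molecule collection.
    """
    if n_compounds % sublibrary_size != 0:
        raise InputError(
            f"sublibrary_size {sublibrary_size} does not divide {n_compounds}"
        )
    idx = [i for i, _ in planted_hits]
    if len(set(idx)) != len(idx):
        raise InputError("duplicate planted hit indices")
    for i, ki in planted_hits:
        if not (0 <= i < n_compounds):
            raise InputError(f"planted index {i} out of range")
        if not (ki > 0):
            raise InputError(f"planted Ki must be > 0, got {ki}")

    rng = np.random.default_rng(seed)
    rrfs = 10.0 ** rng.uniform(math.log10(0.05), math.log10(5.0), n_compounds)
    planted = dict(planted_hits)
    n_sub = n_compounds // sublibrary_size

    rows = []
    truth = GroundTruth()
    for i in range(n_compounds):
        cid = f"C{i + 1:04d}"
        sl = f"SL{i // sublibrary_size + 1}"
        ki = planted.get(i)
        rows.append(
            {
                "compound_id": cid,
                "name": cid,
                "sublibrary_id": sl,
                "conc_nM": component_conc,
                "rrf": round(float(rrfs[i]), 6),
                "true_ki_nM": ki,
                "koff_s": None,
            }
        )
        truth.compounds[cid] = CompoundTruth(
            ki_nM=ki,
            koff_s=None,
            rrf=float(rows[-1]["rrf"]),
            nonspecific_level_nM=0.0,  # filled by simulate_screen
        )
    assert len({r["sublibrary_id"] for r in rows}) == n_sub
    return pd.DataFrame(rows), truth


def _library_frame(library) -> pd.DataFrame:
    if isinstance(library, pd.DataFrame):
        return library
    raise InputError("library must be the DataFrame produced by generate_library "
                     "or read by io.read_library")


def simulate_screen(
    library: pd.DataFrame,
    assay_config: AssayConfig,
    sim_config: SimulationConfig,
    *,
    include_standards: bool = True,
    plate_id: str = "P1",
    sublibrary_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one plate of the screening binding experiment.

    Emits the measurements.csv schema: calibration standards for the reporter,
    a shared control triplicate, and total/nonspecific triplicates per
    sublibrary with rows for the reporter and every library component.
    A library compound whose id equals the reporter id adds its concentration
    to the reporter pool (the scenario that produces anomalously high
    remaining binding).  ``sublibrary_ids`` restricts simulation to a subset
    (e.g. a reduced sublibrary appended to the library frame).
    """
    lib = _library_frame(library)
    rng = np.random.default_rng(sim_config.seed)
    cfg, sim = assay_config, sim_config
    sigma = sim.sigma

    def noisy(x: float) -> float:
        if sigma == 0.0:
            return x
        return x * math.exp(rng.normal(0.0, sigma))

    def area_rows(base: dict, analyte_id: str, conc_lc: float, rrf: float) -> dict:
        area = rrf * conc_lc * AREA_PER_NM
        is_area = cfg.is_conc_lcms * AREA_PER_NM
        return {
            **base,
            "analyte_id": analyte_id,
            "peak_area": noisy(area),
            "is_peak_area": noisy(is_area),
        }

    truth = GroundTruth()
    rows: list[dict] = []

    # --- per-compound truth -------------------------------------------------
    comp_info: dict[str, dict] = {}
    for r in lib.itertuples():
        cid = str(r.compound_id)
        ki = None if pd.isna(r.true_ki_nM) else float(r.true_ki_nM)
        koff = None if pd.isna(r.koff_s) else float(r.koff_s)
        assumed = False
        if ki is not None and koff is None:
            koff = koff_from_kd(ki, sim.kon_default)
            assumed = True
        rrf = (
            sim.response_factor_default
            if pd.isna(r.rrf)
            else float(r.rrf)
        )
        conc = float(r.conc_nM)
        ns_coeff = sim.nonspecific_overrides.get(cid, sim.nonspecific_coeff)
        ns_level = ns_coeff * conc * sim.ns_wash_retention
        comp_info[cid] = {
            "sublibrary_id": str(r.sublibrary_id),
            "conc": conc,
            "ki": ki,
            "koff": koff,
            "rrf": rrf,
            "ns_level": ns_level,
        }
        truth.compounds[cid] = CompoundTruth(
            ki_nM=ki, koff_s=koff, rrf=rrf,
            nonspecific_level_nM=ns_level, koff_assumed=assumed,
        )

    reporter_ns_level = (
        sim.nonspecific_overrides.get(cfg.reporter_id, sim.nonspecific_coeff)
        * cfg.reporter_conc
        * sim.ns_wash_retention
    )
    rep_retention = math.exp(-cfg.reporter_koff * cfg.wash_time)

    # --- calibration standards ----------------------------------------------
    if include_standards:
        for level in sim.calibration_levels:
            rows.append(
                area_rows(
                    {
                        "plate_id": plate_id,
                        "sublibrary_id": "CAL",
                        "condition": "standard",
                        "standard_conc_nM": level,
                        "replicate": 1,
                    },
                    cfg.reporter_id,
                    level,
                    1.0,
                )
            )

    def sample_rows(sl_id: str, condition: str, members: list[str]) -> None:
        """Simulate one condition (triplicate) of one sublibrary (or control)."""
        binders = [c for c in members if comp_info[c]["ki"] is not None]
        reporter_total = cfg.reporter_conc + sum(
            comp_info[c]["conc"] for c in members if c == cfg.reporter_id
        )
        ligands = [LigandSite(cfg.reporter_id, reporter_total, cfg.reporter_kd)]
        ligands += [
            LigandSite(c, comp_info[c]["conc"], comp_info[c]["ki"])
            for c in binders
            if c != cfg.reporter_id
        ]
        if condition == "nonspecific" or condition == "control_nonspecific":
            ligands.append(LigandSite(_BLOCKER_ID, cfg.blocker_conc, cfg.blocker_ki))
        state = solve_equilibrium(cfg.target_conc, ligands)

        pre, post = {}, {}
        pre[cfg.reporter_id] = state.bound(cfg.reporter_id)
        post[cfg.reporter_id] = (
            pre[cfg.reporter_id] * rep_retention + reporter_ns_level
        )
        for c in members:
            if c == cfg.reporter_id:
                continue
            info = comp_info[c]
            bound = state.bound(c) if info["ki"] is not None and c != cfg.reporter_id else 0.0
            retention = (
                math.exp(-info["koff"] * cfg.wash_time) if info["koff"] else 1.0
            )
            pre[c] = bound
            post[c] = bound * retention + info["ns_level"]

        truth.samples.append(
            {
                "plate_id": plate_id,
                "sublibrary_id": sl_id,
                "condition": condition,
                "bound_pre_wash_nM": {k: float(v) for k, v in pre.items()},
                "retained_post_wash_nM": {k: float(v) for k, v in post.items()},
            }
        )
        for rep_i in range(1, cfg.replicates + 1):
            base = {
                "plate_id": plate_id,
                "sublibrary_id": sl_id,
                "condition": condition,
                "standard_conc_nM": np.nan,
                "replicate": rep_i,
            }
            rows.append(
                area_rows(
                    base, cfg.reporter_id,
                    post[cfg.reporter_id] / cfg.dilution_factor, 1.0,
                )
            )
            for c in members:
                if c == cfg.reporter_id:
                    continue
                rows.append(
                    area_rows(
                        base, c, post[c] / cfg.dilution_factor,
                        comp_info[c]["rrf"],
                    )
                )

    # shared no-library control triplicate
    sample_rows("CTRL", "control_total", [])

    wanted = (
        list(dict.fromkeys(lib["sublibrary_id"].astype(str)))
        if sublibrary_ids is None
        else list(sublibrary_ids)
    )
    for sl_id in wanted:
        members = [
            str(r.compound_id)
            for r in lib.itertuples()
            if str(r.sublibrary_id) == sl_id
        ]
        if not members:
            raise InputError(f"no library rows for sublibrary {sl_id!r}")
        sample_rows(sl_id, "total", members)
        sample_rows(sl_id, "nonspecific", members)

    measurements = pd.DataFrame(rows)
    return measurements, truth


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------

# Triplicate normalised-area summaries (mean, sd; n = 3) for one 16-compound
# sublibrary assayed three times: total and nonspecific binding per compound
# per experiment.  One compound is below the MRM quantification limit (None).
# Two compounds are genuine target binders; the rest scatter around equal
# total/nonspecific levels spanning three orders of magnitude of response.
TABLE1_SUMMARIES: dict[str, list[tuple[tuple[float, float], tuple[float, float]] | None]] = {
    "4-(4-chlorophenyl)-piperidin-4-ol": [None, None, None],
    "8-OH DPAT": [
        ((0.177, 0.006), (0.193, 0.004)),
        ((0.303, 0.012), (0.283, 0.042)),
        ((0.176, 0.012), (0.162, 0.027)),
    ],
    "chlorpromazine": [
        ((6.590, 0.156), (6.370, 0.198)),
        ((6.173, 0.693), (5.663, 0.597)),
        ((6.147, 0.314), (6.280, 0.928)),
    ],
    "DDPM2330": [
        ((0.771, 0.003), (0.738, 0.002)),
        ((0.876, 0.048), (0.813, 0.031)),
        ((0.490, 0.038), (0.368, 0.021)),
    ],
    "DDPM2565": [
        ((0.571, 0.040), (0.119, 0.006)),
        ((0.799, 0.063), (0.335, 0.011)),
        ((0.454, 0.012), (0.069, 0.017)),
    ],
    "doxepin": [
        ((0.705, 0.025), (0.666, 0.008)),
        ((0.932, 0.064), (0.827, 0.096)),
        ((0.433, 0.056), (0.404, 0.084)),
    ],
    "fenoterol": [
        ((0.041, 0.008), (0.041, 0.002)),
        ((0.034, 0.002), (0.030, 0.004)),
        ((0.021, 0.003), (0.021, 0.002)),
    ],
    "ketoprofen": [
        ((0.004, 0.000), (0.005, 0.000)),
        ((0.003, 0.000), (0.003, 0.000)),
        ((0.004, 0.000), (0.004, 0.001)),
    ],
    "meclozine": [
        ((4.937, 0.861), (6.095, 0.205)),
        ((5.307, 0.931), (5.253, 1.007)),
        ((5.188, 0.271), (5.523, 0.934)),
    ],
    "metoclopramide": [
        ((0.370, 0.013), (0.390, 0.028)),
        ((0.503, 0.027), (0.457, 0.054)),
        ((0.317, 0.017), (0.281, 0.042)),
    ],
    "oxazepam": [
        ((0.132, 0.001), (0.130, 0.026)),
        ((0.120, 0.020), (0.111, 0.007)),
        ((0.097, 0.014), (0.106, 0.024)),
    ],
    "piroxicam": [
        ((0.054, 0.000), (0.060, 0.005)),
        ((0.034, 0.001), (0.034, 0.003)),
        ((0.040, 0.001), (0.037, 0.004)),
    ],
    "procaine": [
        ((0.073, 0.003), (0.074, 0.006)),
        ((0.092, 0.003), (0.082, 0.010)),
        ((0.073, 0.005), (0.063, 0.008)),
    ],
    "roxithromycin": [
        ((0.020, 0.003), (0.021, 0.001)),
        ((0.003, 0.001), (0.003, 0.001)),
        ((0.012, 0.001), (0.010, 0.001)),
    ],
    "sulpiride": [
        ((0.054, 0.002), (0.056, 0.004)),
        ((0.068, 0.002), (0.061, 0.009)),
        ((0.055, 0.003), (0.047, 0.003)),
    ],
    "telmisartan": [
        ((3.853, 0.130), (3.405, 0.106)),
        ((2.577, 0.326), (2.290, 0.340)),
        ((2.257, 0.122), (2.183, 0.455)),
    ],
}


def make_fixture(name: str):
    """Deterministic bundled datasets.

    - ``"table1"``: per-compound, per-experiment (total, nonspecific)
      :class:`TripletSummary` pairs for a 16-compound sublibrary assayed three
      times (summary statistics set exactly, no sampling); compounds below the
      quantification limit map to ``None``.
    - ``"null16"``: one 16-compound sublibrary with no binders — library
      frame, measurement table and ground truth at the default noise level.
    - ``"tocris-like"``: an 80 x 16 = 1,280-compound library frame with four
      planted high-affinity inhibitors spread across four sublibraries, plus
      its ground truth (simulate with :func:`simulate_screen` as needed).
    """
    if name == "table1":
        out: dict[str, list[tuple[TripletSummary, TripletSummary] | None]] = {}
        for comp, experiments in TABLE1_SUMMARIES.items():
            series = []
            for pair in experiments:
                if pair is None:
                    series.append(None)
                    continue
                (tm, tsd), (nm, nsd) = pair
                series.append(
                    (
                        TripletSummary(comp, "total", tm, tsd, 3),
                        TripletSummary(comp, "nonspecific", nm, nsd, 3),
                    )
                )
            out[comp] = series
        return out
    if name == "null16":
        lib, _ = generate_library(16, 16, [], seed=161616)
        meas, truth = simulate_screen(
            lib, AssayConfig(), SimulationConfig(seed=161616)
        )
        return {"library": lib, "measurements": meas, "truth": truth}
    if name == "tocris-like":
        planted = [(96, 30.0), (131, 20.0), (211, 25.0), (600, 40.0)]
        lib, truth = generate_library(1280, 16, planted, seed=12801280)
        return {"library": lib, "truth": truth, "planted": planted}
    raise InputError(f"unknown fixture {name!r}")
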