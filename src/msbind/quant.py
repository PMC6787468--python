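"""MRM quantification: IS normalisation, calibration, RRFs, bound-concentration
estimates and quantifier-transition selection.

Peak areas from the triple-quadrupole MRM runs are never used raw: every
analyte area is divided by the area of the isotope-labelled internal standard
(IS) acquired in the same run, which cancels injection-to-injection ESI drift.
The reporter ligand is quantified against a per-experiment calibration line of
normalised area on concentration.  Library components are instead converted
through their relative response factor (RRF): the normalised area produced per
unit analyte concentration relative to the IS, measured on matrix standards at
the IS concentration (1 nM), so that at equal concentrations the RRF is the
normalised area itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import FitError, InputError

__all__ = [
    "PeakPair",
    "CalibrationCurve",
    "ResponseFactor",
    "TransitionRecord",
    "BoundConcEstimate",
    "normalized_area",
    "fit_calibration",
    "quantify",
    "compute_rrf",
    "bound_conc_estimate",
    "select_quant_transition",
]


@dataclass(frozen=True)
class PeakPair:
    """Integrated analyte and internal-standard peak areas from one run."""

    analyte_area: float
    is_area: float

    def __post_init__(self):
        if not (self.analyte_area >= 0):
            raise InputError(f"analyte_area must be >= 0, got {self.analyte_area}")
        if not (self.is_area > 0):
            raise InputError(f"is_area must be > 0, got {self.is_area}")


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line of normalised area on concentration, with its fitted range."""

    slope: float  # normalised area per nM
    intercept: float
    fit_range: tuple[float, float]  # (min, max) concentration, nM


@dataclass(frozen=True)
class ResponseFactor:
    """Relative response factor of one analyte vs. the internal standard."""

    analyte_id: str
    rrf: float

    def __post_init__(self):
        if not (self.rrf > 0):
            raise InputError(
                f"analyte {self.analyte_id!r}: rrf must be > 0, got {self.rrf}"
            )


@dataclass(frozen=True)
class TransitionRecord:
    """One MRM transition of an analyte with its S/N at the 1 nM matrix standard."""

    analyte_id: str
    transition: str  # e.g. "403->154"
    signal_to_noise: float

    def __post_init__(self):
        if not (self.signal_to_noise >= 0):
            raise InputError(
                f"signal_to_noise must be >= 0, got {self.signal_to_noise}"
            )


@dataclass(frozen=True)
class BoundConcEstimate:
    """RRF-based specific-binding concentration estimate.

    ``conc_lc_nM`` is the concentration in the LC sample; ``conc_sample_nM``
    scales it back to the binding sample by the elution dilution factor.
    ``delta_na`` is kept raw (possibly negative) for the statistics; the
    concentration itself is floored at zero (``floored`` marks that case).
    ``estimable`` is False when no RRF was available.
    """

    delta_na: float
    conc_lc_nM: float | None
    conc_sample_nM: float | None
    floored: bool
    estimable: bool


def normalized_area(p: PeakPair) -> float:
    """Analyte area divided by internal-standard area."""
    return p.analyte_area / p.is_area


#: S/N threshold above which a transition supports quantification (LLOQ rule)
LLOQ_SN = 5.0


def fit_calibration(
    standards: Sequence[tuple[float, float]]
) -> CalibrationCurve:
    """Fit the per-experiment calibration line.

    ``standards`` are (concentration nM, normalised area) pairs; the fit is
    unweighted ordinary least squares.  At least two distinct concentrations
    are required and the slope must come out positive.
    """
    if len(standards) < 2:
        raise FitError(f"need >= 2 calibration points, got {len(standards)}")
    conc = np.asarray([s[0] for s in standards], dtype=float)
    na = np.asarray([s[1] for s in standards], dtype=float)
    if np.ptp(conc) == 0:
        raise FitError("calibration standards have zero concentration spread")
    res = stats.linregress(conc, na)
    if not (res.slope > 0):
        raise FitError(f"calibration slope must be > 0, got {res.slope:.4g}")
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        fit_range=(float(conc.min()), float(conc.max())),
    )


def quantify(
    curve: CalibrationCurve, na: float, *, warn_extrapolation: bool = True
) -> float:
    """Invert the calibration line: concentration = (na - intercept)/slope.

    Values outside the fitted range are extrapolated with a warning, never
    rejected — binding samples routinely sit below the lowest standard.
    """
    conc = (na - curve.intercept) / curve.slope
    if warn_extrapolation and not (
        curve.fit_range[0] <= conc <= curve.fit_range[1]
    ):
        import warnings

        warnings.warn(
            f"quantified concentration {conc:.4g} nM outside calibrated range "
            f"{curve.fit_range}",
            stacklevel=2,
        )
    return conc


def compute_rrf(na: float, analyte_conc: float, is_conc: float, analyte_id: str = "") -> ResponseFactor:
    """RRF from a matrix standard: rrf = na * is_conc / analyte_conc.

    When analyte and IS are at the same concentration the RRF equals the
    normalised area itself.
    """
    if not (analyte_conc > 0):
        raise InputError(f"analyte_conc must be > 0, got {analyte_conc}")
    if not (is_conc > 0):
        raise InputError(f"is_conc must be > 0, got {is_conc}")
    return ResponseFactor(analyte_id=analyte_id, rrf=na * is_conc / analyte_conc)


def bound_conc_estimate(
    delta_na: float,
    rf: ResponseFactor | None,
    is_conc_lcms: float,
    dilution_factor: float,
) -> BoundConcEstimate:
    """Specific-binding concentration from a total-minus-nonspecific
    normalised-area difference, via the analyte's RRF.

    LC-sample concentration = max(delta_na, 0)/rrf * is_conc; the binding-sample
    value multiplies by the elution dilution factor.  With no RRF the delta is
    reported alone (``estimable=False``).
    """
    if not (dilution_factor > 0):
        raise InputError(f"dilution_factor must be > 0, got {dilution_factor}")
    if rf is None:
        return BoundConcEstimate(
            delta_na=delta_na,
            conc_lc_nM=None,
            conc_sample_nM=None,
            floored=False,
            estimable=False,
        )
    if not (is_conc_lcms > 0):
        raise InputError(f"is_conc_lcms must be > 0, got {is_conc_lcms}")
    floored = delta_na < 0
    conc_lc = max(delta_na, 0.0) / rf.rrf * is_conc_lcms
    return BoundConcEstimate(
        delta_na=delta_na,
        conc_lc_nM=conc_lc,
        conc_sample_nM=conc_lc * dilution_factor,
        floored=floored,
        estimable=True,
    )


def select_quant_transition(
    records: Sequence[TransitionRecord],
) -> tuple[TransitionRecord, bool]:
    """Pick the quantifier transition: highest S/N, first wins on ties.

    The analyte counts as quantifiable only if the best S/N exceeds the
    LLOQ criterion (S/N > 5).
    """
    if not records:
        raise InputError("need at least one transition record")
    best = records[0]
    for rec in records[1:]:
        if rec.signal_to_noise > best.signal_to_noise:
            best = rec
    return best, best.signal_to_noise > LLOQ_SN
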