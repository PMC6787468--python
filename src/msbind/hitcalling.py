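"""Activity assessment and hit-calling statistics.

Two decisions drive the screen.  A *sublibrary* is active when the specific
binding of the reporter ligand in its presence falls below 50% of the
no-library control (strict inequality; anomalously high values, such as a
sublibrary containing the reporter compound itself, are flagged separately).
A *component* of an active sublibrary is a hit when its total binding
significantly exceeds its non-specific binding in a one-sided two-sample
Student t-test on the triplicate normalised areas (pooled variance,
df = n1 + n2 - 2, one-sided confidence level 97.5%, i.e. alpha = 0.025,
critical value 2.776 at df = 4).

Summary statistics (mean, sd, n) are first-class inputs so published triplicate
summaries can be tested directly; raw replicate values, when available, take
precedence and the summary is recomputed from them.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from .errors import InputError, UndefinedRatioError

__all__ = [
    "TripletSummary",
    "HitCall",
    "ActivityResult",
    "t_quantile",
    "one_sided_t",
    "count_hit_experiments",
    "remaining_specific_binding",
    "classify_activity",
]

#: variance floor guarding the pooled-variance division only
_VAR_EPS = 1e-12


@dataclass(frozen=True)
class TripletSummary:
    """Replicate summary (mean, sd, n) of one analyte under one condition."""

    analyte_id: str
    condition: str  # "total" | "nonspecific" | "control_total"
    mean: float
    sd: float
    n: int
    values: tuple[float, ...] | None = None

    def __post_init__(self):
        if not (self.sd >= 0):
            raise InputError(f"sd must be >= 0, got {self.sd}")
        if self.n < 2:
            raise InputError(f"need n >= 2 replicates, got {self.n}")
        if self.values is not None and len(self.values) != self.n:
            raise InputError(
                f"{len(self.values)} raw values inconsistent with n={self.n}"
            )

    @classmethod
    def from_values(
        cls, analyte_id: str, condition: str, values: Sequence[float]
    ) -> "TripletSummary":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise InputError(f"need >= 2 replicate values, got {arr.size}")
        return cls(
            analyte_id=analyte_id,
            condition=condition,
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)),
            n=int(arr.size),
            values=tuple(float(v) for v in arr),
        )


@dataclass(frozen=True)
class HitCall:
    """Outcome of the one-sided total-vs-nonspecific test for one analyte."""

    analyte_id: str
    delta: float
    t_stat: float
    df: int
    critical_value: float
    significant: bool


@dataclass(frozen=True)
class ActivityResult:
    """Remaining specific reporter binding of one sublibrary and its flags."""

    sublibrary_id: str
    remaining_pct: float
    remaining_sd: float
    active: bool
    anomaly: bool


@functools.lru_cache(maxsize=256)
def t_quantile(df: int, p: float) -> float:
    """One-sided quantile of Student's t distribution.

    Inverts the t CDF through the regularised incomplete beta function:
    for t >= 0, P(T <= t) = 1 - I_x(df/2, 1/2)/2 with x = df/(df + t^2), so
    x = I^-1(df/2, 1/2; 2(1-p)) and t = sqrt(df (1-x)/x).  Valid for
    1 <= df <= 200, which covers every replicate design the assay uses.
    """
    if not (1 <= df <= 200):
        raise InputError(f"df must be in [1, 200], got {df}")
    if not (0.0 < p < 1.0):
        raise InputError(f"p must be in (0, 1), got {p}")
    if p == 0.5:
        return 0.0
    upper = max(p, 1.0 - p)
    x = special.betaincinv(df / 2.0, 0.5, 2.0 * (1.0 - upper))
    t = math.sqrt(df * (1.0 - x) / x)
    return t if p > 0.5 else -t


def one_sided_t(
    total: TripletSummary,
    nonspecific: TripletSummary,
    confidence_level: float = 97.5,
    *,
    welch: bool = False,
) -> HitCall:
    """One-sided two-sample Student t-test of total > nonspecific binding.

    Pooled variance by default (equal-n triplicates); set ``welch=True`` for
    the unequal-variance form with Welch-Satterthwaite df.  ``confidence_level``
    is the one-sided confidence in percent (97.5 -> alpha 0.025).

    Degenerate zero-variance inputs are resolved by sign of the difference:
    no difference -> not significant; a positive difference with no scatter is
    significant with the t statistic reported as +inf.
    """
    if total.analyte_id != nonspecific.analyte_id:
        raise InputError(
            f"analyte mismatch: {total.analyte_id!r} vs {nonspecific.analyte_id!r}"
        )
    if not (0.0 < confidence_level < 100.0):
        raise InputError(f"confidence_level must be in (0, 100), got {confidence_level}")

    n1, n2 = total.n, nonspecific.n
    delta = total.mean - nonspecific.mean

    if total.sd == 0.0 and nonspecific.sd == 0.0:
        t_stat = math.inf if delta > 0 else (-math.inf if delta < 0 else 0.0)
        df = n1 + n2 - 2
        crit = t_quantile(df, confidence_level / 100.0)
        return HitCall(
            analyte_id=total.analyte_id,
            delta=delta,
            t_stat=t_stat,
            df=df,
            critical_value=crit,
            significant=delta > 0,
        )

    if welch:
        v1, v2 = total.sd**2 / n1, nonspecific.sd**2 / n2
        se2 = max(v1 + v2, _VAR_EPS)
        df = int(
            round(se2**2 / max(v1**2 / (n1 - 1) + v2**2 / (n2 - 1), _VAR_EPS**2))
        )
        df = max(1, min(df, n1 + n2 - 2))
        t_stat = delta / math.sqrt(se2)
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * total.sd**2 + (n2 - 1) * nonspecific.sd**2) / df
        # the both-zero case never reaches here, so sp2 > 0; the floor only
        # guards against underflow to exactly 0
        t_stat = delta / math.sqrt(max(sp2, _VAR_EPS) * (1.0 / n1 + 1.0 / n2))

    crit = t_quantile(df, confidence_level / 100.0)
    return HitCall(
        analyte_id=total.analyte_id,
        delta=delta,
        t_stat=t_stat,
        df=df,
        critical_value=crit,
        significant=(delta > 0) and (t_stat > crit),
    )


def count_hit_experiments(calls: Sequence[HitCall]) -> int:
    """Number of repeated experiments in which one analyte was significant."""
    if not calls:
        raise InputError("need at least one hit call")
    ids = {c.analyte_id for c in calls}
    if len(ids) > 1:
        raise InputError(f"hit calls mix analytes: {sorted(ids)}")
    return sum(1 for c in calls if c.significant)


def remaining_specific_binding(
    total_lib: Sequence[float],
    ns_lib: Sequence[float],
    control_total: Sequence[float],
    control_ns: Sequence[float],
) -> tuple[float, float]:
    """Remaining specific reporter binding, as (percent mean, percent sd).

    Specific binding with the sublibrary is each total replicate minus the
    mean nonspecific level; the control's specific binding is formed the same
    way.  The percentage is the ratio of means; the sd comes from the
    per-replicate ratios against the (fixed) control mean.
    """
    total_lib = np.asarray(total_lib, dtype=float)
    ns_lib = np.asarray(ns_lib, dtype=float)
    control_total = np.asarray(control_total, dtype=float)
    control_ns = np.asarray(control_ns, dtype=float)
    for name, arr in [
        ("total_lib", total_lib),
        ("ns_lib", ns_lib),
        ("control_total", control_total),
        ("control_ns", control_ns),
    ]:
        if arr.size == 0:
            raise InputError(f"{name} replicate set is empty")

    specific_with = total_lib - ns_lib.mean()
    specific_control_mean = control_total.mean() - control_ns.mean()
    if specific_control_mean <= 0:
        raise UndefinedRatioError(
            f"control specific binding is {specific_control_mean:.4g} <= 0"
        )
    ratios = 100.0 * specific_with / specific_control_mean
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return float(ratios.mean()), sd


def classify_activity(
    remaining_pct: float,
    config=None,
    *,
    sublibrary_id: str = "",
    remaining_sd: float = 0.0,
    activity_threshold_pct: float | None = None,
    anomaly_threshold_pct: float | None = None,
) -> ActivityResult:
    """Apply the activity and anomaly thresholds to a remaining-binding value.

    Active: remaining < 50% (strict, configurable through ``config`` or the
    keyword overrides).  Anomaly: remaining > 150%, e.g. when the sublibrary
    contains the reporter compound itself and binding exceeds the control.
    """
    if not math.isfinite(remaining_pct):
        raise InputError(f"remaining_pct must be finite, got {remaining_pct}")
    act = activity_threshold_pct
    ano = anomaly_threshold_pct
    if config is not None:
        act = config.activity_threshold_pct if act is None else act
        ano = config.anomaly_threshold_pct if ano is None else ano
    act = 50.0 if act is None else act
    ano = 150.0 if ano is None else ano
    if not (act < ano):
        raise InputError(
            f"activity threshold {act} must lie below anomaly threshold {ano}"
        )
    return ActivityResult(
        sublibrary_id=sublibrary_id,
        remaining_pct=remaining_pct,
        remaining_sd=remaining_sd,
        active=remaining_pct < act,
        anomaly=remaining_pct > ano,
    )
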