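"""Single-site competitive mass-action equilibrium model.

Several ligands (a reporter such as NO711 plus library components and,
optionally, a blocking ligand in large excess) compete for one binding site on
a target present at a concentration comparable to the reporter's Kd, so both
target and ligand depletion are modelled explicitly.  At equilibrium each
ligand ``i`` obeys

    bound_i = T_free * L_free_i / Kd_i

together with conservation of target and of every ligand.  Eliminating the
ligand concentrations leaves a single strictly increasing function of the free
target concentration,

    f(T_free) = T_free * (1 + sum_i L_tot_i / (Kd_i + T_free)) - T_total,

whose unique root on [0, T_total] determines the whole state.

The module also provides the Cheng-Prusoff IC50/Ki conversion for a
competitive inhibitor assayed against a reporter at known concentration and
Kd, and the first-order dissociation loss incurred while bound complexes are
washed on the filter after vacuum filtration.

All concentrations are in nM, times in seconds, rates in s^-1; ``kon`` is the
customary M^-1 s^-1 and is converted at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.optimize import brentq

from .errors import InputError, UndefinedRatioError

__all__ = [
    "LigandSite",
    "BoundLigand",
    "EquilibriumState",
    "KineticSpec",
    "solve_equilibrium",
    "reporter_remaining_pct",
    "ki_from_ic50",
    "ic50_from_ki",
    "wash_retention",
    "koff_from_kd",
]

#: conservation tolerance, as a fraction of max(1 nM, total target)
RESIDUAL_RTOL = 1e-9


@dataclass(frozen=True)
class LigandSite:
    """One ligand competing for the single target site.

    ``kd`` is the equilibrium dissociation constant in nM; for a competitor it
    is the inhibition constant Ki.  ``total_conc`` may be zero (the ligand then
    contributes nothing).
    """

    ligand_id: str
    total_conc: float  # nM
    kd: float  # nM

    def __post_init__(self):
        if not (self.total_conc >= 0):
            raise InputError(
                f"ligand {self.ligand_id!r}: total_conc must be >= 0, "
                f"got {self.total_conc}"
            )
        if not (self.kd > 0):
            raise InputError(
                f"ligand {self.ligand_id!r}: kd must be > 0, got {self.kd}"
            )


@dataclass(frozen=True)
class BoundLigand:
    """Solved free/bound split of one ligand (nM)."""

    ligand_id: str
    free_conc: float
    bound_conc: float


@dataclass(frozen=True)
class EquilibriumState:
    """Solved equilibrium: free target, per-ligand free/bound, residual (nM)."""

    free_target: float
    ligands: tuple[BoundLigand, ...]
    residual: float

    def bound(self, ligand_id: str) -> float:
        """Bound concentration (nM) of one ligand, by id."""
        for lig in self.ligands:
            if lig.ligand_id == ligand_id:
                return lig.bound_conc
        raise KeyError(ligand_id)

    @property
    def total_bound(self) -> float:
        return sum(lig.bound_conc for lig in self.ligands)


@dataclass(frozen=True)
class KineticSpec:
    """First-order dissociation kinetics of a target-ligand complex.

    ``kon`` (M^-1 s^-1) is optional; when present, koff/kon is the kinetically
    implied Kd and can be checked against an equilibrium value with
    :meth:`check_kd`.
    """

    koff: float  # s^-1
    kon: float | None = None  # M^-1 s^-1

    def __post_init__(self):
        if not (self.koff > 0):
            raise InputError(f"koff must be > 0, got {self.koff}")
        if self.kon is not None and not (self.kon > 0):
            raise InputError(f"kon must be > 0, got {self.kon}")

    @property
    def implied_kd_nM(self) -> float | None:
        """Kd = koff/kon, in nM, when kon is known."""
        if self.kon is None:
            return None
        return self.koff / self.kon * 1e9

    def check_kd(self, kd_nM: float, rtol: float = 0.01) -> None:
        """Raise if koff/kon disagrees with ``kd_nM`` by more than ``rtol``."""
        implied = self.implied_kd_nM
        if implied is None:
            return
        if abs(implied - kd_nM) > rtol * kd_nM:
            raise InputError(
                f"koff/kon implies Kd {implied:.4g} nM, inconsistent with "
                f"{kd_nM:.4g} nM beyond {rtol:.0%}"
            )


def solve_equilibrium(
    target_total: float, ligands: Sequence[LigandSite] | Iterable[LigandSite]
) -> EquilibriumState:
    """Solve the coupled competitive equilibrium with full depletion.

    Finds the unique root of ``f(T_free)`` (see module docstring) on
    ``[0, target_total]`` by bracketed root search; f is strictly increasing in
    T_free so the root is unique.  The returned state satisfies target and
    per-ligand conservation to within ``RESIDUAL_RTOL * max(1, target_total)``.
    """
    ligands = list(ligands)
    if not (target_total >= 0):
        raise InputError(f"target_total must be >= 0, got {target_total}")
    for lig in ligands:
        if not isinstance(lig, LigandSite):
            lig = LigandSite(*lig)  # re-validate tuples defensively

    def f(t_free: float) -> float:
        return (
            t_free * (1.0 + sum(l.total_conc / (l.kd + t_free) for l in ligands))
            - target_total
        )

    if target_total == 0.0 or all(l.total_conc == 0.0 for l in ligands):
        t_free = target_total
    else:
        # f(0) = -T_total < 0 and f(T_total) >= 0: the bracket always holds.
        t_free = brentq(
            f, 0.0, target_total, xtol=1e-15, rtol=8.9e-16, maxiter=200
        )

    solved = tuple(
        BoundLigand(
            ligand_id=l.ligand_id,
            free_conc=l.total_conc * l.kd / (l.kd + t_free),
            bound_conc=t_free * l.total_conc / (l.kd + t_free),
        )
        for l in ligands
    )
    residual = abs(t_free + sum(b.bound_conc for b in solved) - target_total)
    tol = RESIDUAL_RTOL * max(1.0, target_total)
    if residual > tol:
        raise ArithmeticError(
            f"equilibrium solver residual {residual:.3g} nM exceeds {tol:.3g} nM"
        )
    return EquilibriumState(free_target=t_free, ligands=solved, residual=residual)


def reporter_remaining_pct(config, competitors: Sequence[LigandSite]) -> float:
    """Percentage of bound reporter remaining in the presence of competitors.

    Both the competitor-free control and the competitor-containing sample are
    solved with full depletion; the ratio of the reporter's bound
    concentrations, times 100, is the remaining binding the assay reports.

    ``config`` is an :class:`~msbind.pipeline.AssayConfig` (or anything with
    ``reporter_conc``, ``reporter_kd`` and ``target_conc`` attributes).
    """
    reporter = LigandSite("reporter", config.reporter_conc, config.reporter_kd)
    control = solve_equilibrium(config.target_conc, [reporter])
    control_bound = control.bound("reporter")
    if control_bound <= 0.0:
        raise UndefinedRatioError("control bound reporter is zero")
    with_comp = solve_equilibrium(
        config.target_conc, [reporter, *competitors]
    )
    return 100.0 * with_comp.bound("reporter") / control_bound


def ki_from_ic50(ic50: float, reporter_conc: float, reporter_kd: float) -> float:
    """Cheng-Prusoff: Ki = IC50 / (1 + [R]/Kd) for a competitive inhibitor."""
    if not (ic50 > 0):
        raise InputError(f"ic50 must be > 0, got {ic50}")
    if not (reporter_kd > 0):
        raise InputError(f"reporter_kd must be > 0, got {reporter_kd}")
    if not (reporter_conc >= 0):
        raise InputError(f"reporter_conc must be >= 0, got {reporter_conc}")
    return ic50 / (1.0 + reporter_conc / reporter_kd)


def ic50_from_ki(ki: float, reporter_conc: float, reporter_kd: float) -> float:
    """Inverse Cheng-Prusoff: IC50 = Ki * (1 + [R]/Kd)."""
    if not (ki > 0):
        raise InputError(f"ki must be > 0, got {ki}")
    if not (reporter_kd > 0):
        raise InputError(f"reporter_kd must be > 0, got {reporter_kd}")
    if not (reporter_conc >= 0):
        raise InputError(f"reporter_conc must be >= 0, got {reporter_conc}")
    return ki * (1.0 + reporter_conc / reporter_kd)


def wash_retention(kinetics: KineticSpec, wash_time: float) -> float:
    """Fraction of bound complex surviving a wash of ``wash_time`` seconds.

    First-order dissociation with no rebinding: exp(-koff * t).
    """
    if wash_time < 0:
        raise InputError(f"wash_time must be >= 0, got {wash_time}")
    return math.exp(-kinetics.koff * wash_time)


def koff_from_kd(kd: float, kon: float) -> float:
    """koff (s^-1) implied by Kd (nM) and kon (M^-1 s^-1): koff = kon * Kd."""
    if not (kd > 0):
        raise InputError(f"kd must be > 0, got {kd}")
    if not (kon > 0):
        raise InputError(f"kon must be > 0, got {kon}")
    return kon * kd * 1e-9
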