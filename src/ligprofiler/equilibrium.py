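"""Exact equilibrium solutions for fibril--ligand binding mixtures.

A fibril is modelled as a set of independent binding-site populations.
Each population belongs to one of two site classes: BS1 (accessible to
both the fluorescent reporter L0 and a dark competitor L1) and BS2
(accessible only to L0).  Within a population, occupancy by the two
ligands is competitive (mutually exclusive); there is no cooperativity,
so every site obeys a 1:1 Langmuir isotherm in the *free* ligand
concentrations.

All concentrations are in nM; fluorescence signals are in arbitrary
units; anisotropy is dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BS1",
    "BS2",
    "LigandDef",
    "SitePopulation",
    "FibrilModel",
    "SpeciesState",
    "EquilibriumError",
    "solve_binary_equilibrium",
    "solve_competition_equilibrium",
    "predict_intensity",
    "predict_anisotropy",
]

BS1 = "BS1"
BS2 = "BS2"

#: relative mass-balance tolerance every solved state must satisfy
MASS_BALANCE_RTOL = 1e-10


class EquilibriumError(ValueError):
    """Raised for invalid inputs or solver failure; carries residuals if any."""

    def __init__(self, message: str, residuals: tuple[float, float] | None = None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class LigandDef:
    """Photophysical definition of one ligand.

    ``role`` is the ligand's role in the assay at hand: ``"reporter"``
    (L0, signal-generating) or ``"competitor"`` (L1, dark).
    ``signal_mode`` selects the readout: ``"intensity"`` for
    solvatochromic reporters, ``"anisotropy"`` for non-solvatochromic
    fluorophores, ``"dark"`` for competitors.
    Brightness values are fluorescence per nM of ligand (arbitrary
    units/nM); ``r_free``/``r_bound`` are only meaningful in
    anisotropy mode.
    """

    name: str
    role: str = "reporter"
    signal_mode: str = "intensity"
    brightness_free: float = 0.0
    brightness_bound: float = 1.0
    r_free: float = 0.05
    r_bound: float = 0.25

    def __post_init__(self) -> None:
        if self.role not in ("reporter", "competitor"):
            raise EquilibriumError(f"unknown ligand role {self.role!r}")
        if self.signal_mode not in ("intensity", "anisotropy", "dark"):
            raise EquilibriumError(f"unknown signal mode {self.signal_mode!r}")
        if self.brightness_free < 0 or self.brightness_bound < 0:
            raise EquilibriumError("brightness values must be >= 0")
        if self.signal_mode == "intensity" and self.brightness_bound <= self.brightness_free:
            raise EquilibriumError(
                "solvatochromic reporter requires brightness_bound > brightness_free"
            )
        if self.signal_mode == "anisotropy" and not (
            0.0 <= self.r_free <= self.r_bound <= 0.4
        ):
            raise EquilibriumError("anisotropy limits must satisfy 0 <= r_free <= r_bound <= 0.4")


@dataclass(frozen=True)
class SitePopulation:
    """One population of identical binding sites on a fibril.

    ``kd`` maps ligand name -> dissociation constant (nM).  A missing
    entry means the ligand does not bind this population (K_d = inf).
    """

    site_class: str
    concentration: float
    kd: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.site_class not in (BS1, BS2):
            raise EquilibriumError(f"unknown site class {self.site_class!r}")
        if self.concentration < 0:
            raise EquilibriumError("site concentration must be >= 0")
        for name, kd in self.kd.items():
            if not kd > 0:
                raise EquilibriumError(f"K_d for {name!r} must be > 0 (got {kd})")

    def kd_for(self, ligand: str) -> float:
        return float(self.kd.get(ligand, math.inf))

    def binds(self, ligand: str) -> bool:
        return ligand in self.kd


@dataclass(frozen=True)
class FibrilModel:
    """Named fibril polymorph: ground-truth site populations for simulation."""

    name: str
    sites: tuple[SitePopulation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        signatures = set()
        for pop in self.sites:
            sig = (pop.site_class, frozenset(pop.kd))
            if sig in signatures:
                raise EquilibriumError(
                    f"fibril {self.name!r}: duplicate population for {sig}"
                )
            signatures.add(sig)

    def validate_competitor_exclusion(self, competitor_names: Iterable[str]) -> None:
        """BS2 must be inaccessible to dark competitor-only ligands."""
        competitors = set(competitor_names)
        for pop in self.sites:
            if pop.site_class == BS2 and competitors & set(pop.kd):
                raise EquilibriumError(
                    f"fibril {self.name!r}: BS2 population carries a competitor K_d"
                )

    def total_sites(self, ligand: str) -> float:
        return sum(p.concentration for p in self.sites if p.binds(ligand))


@dataclass(frozen=True)
class SpeciesState:
    """Solved equilibrium composition of a two-ligand / multi-site mixture.

    ``bound`` maps (ligand name, site class) -> bound concentration in nM,
    summed over populations of that class.  ``occupancy`` maps site class
    -> total fractional occupancy of that class.
    """

    free_l0: float
    free_l1: float
    bound: Mapping[tuple[str, str], float]
    occupancy: Mapping[str, float]

    def total_bound(self, ligand: str) -> float:
        return sum(v for (lig, _), v in self.bound.items() if lig == ligand)


def solve_binary_equilibrium(l_total: float, s_total: float, kd: float) -> float:
    """Bound complex concentration for a single ligand and a single site class.

    Solves the mass-balance quadratic
    ``b**2 - (L + S + Kd) * b + L * S = 0`` and returns the physical root
    ``0 <= b <= min(L, S)``, using the numerically stable form
    ``b = 2 L S / (p + sqrt(p**2 - 4 L S))`` with ``p = L + S + Kd``.
    """
    if l_total < 0 or s_total < 0:
        raise EquilibriumError("totals must be >= 0")
    if not kd > 0:
        raise EquilibriumError("kd must be > 0")
    if l_total == 0 or s_total == 0:
        return 0.0
    p = l_total + s_total + kd
    disc = p * p - 4.0 * l_total * s_total
    # p**2 >= 4 L S + kd**2 analytically; clip rounding noise
    disc = max(disc, 0.0)
    return 2.0 * l_total * s_total / (p + math.sqrt(disc))


def _bound_at(free: Mapping[str, float], pop: SitePopulation) -> dict[str, float]:
    """Competitive Langmuir occupancy of one population at given free concs."""
    denom = 1.0
    terms = {}
    for lig, f in free.items():
        kd = pop.kd_for(lig)
        if math.isfinite(kd) and f > 0:
            t = f / kd
            terms[lig] = t
            denom += t
    return {lig: pop.concentration * t / denom for lig, t in terms.items()}


def _free_l0_given_l1(
    l0_total: float, f1: float, sites: tuple[SitePopulation, ...], l0: str, l1: str
) -> float:
    """Solve the inner (L0) mass balance at fixed free L1 by bisection."""
    if l0_total == 0:
        return 0.0

    def resid(f0: float) -> float:
        b = 0.0
        for pop in sites:
            b += _bound_at({l0: f0, l1: f1}, pop).get(l0, 0.0)
        return f0 + b - l0_total

    # resid is strictly increasing in f0; root is in (0, l0_total]
    lo, hi = 0.0, l0_total
    if resid(hi) <= 0:
        return hi
    return brentq(resid, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)


def solve_competition_equilibrium(
    l0_total: float,
    l1_total: float,
    sites: Iterable[SitePopulation],
    l0_name: str = "L0",
    l1_name: str = "L1",
) -> SpeciesState:
    """Coupled two-ligand equilibrium over any number of site populations.

    Nested root-find on the two free-ligand concentrations: the inner L0
    balance is solved by bisection at fixed free L1, and the outer L1
    balance by bisection over free L1 (both residuals are strictly
    monotone, so the solution is unique and the result is independent of
    any initial guess).  Conservation is enforced to a relative residual
    of 1e-10.
    """
    sites = tuple(sites)
    if l0_total < 0 or l1_total < 0:
        raise EquilibriumError("ligand totals must be >= 0")
    if not sites:
        raise EquilibriumError("at least one site population is required")

    def outer_resid(f1: float) -> float:
        f0 = _free_l0_given_l1(l0_total, f1, sites, l0_name, l1_name)
        b1 = 0.0
        for pop in sites:
            b1 += _bound_at({l0_name: f0, l1_name: f1}, pop).get(l1_name, 0.0)
        return f1 + b1 - l1_total

    if l1_total == 0:
        f1 = 0.0
    elif outer_resid(l1_total) <= 0:
        f1 = l1_total
    else:
        f1 = brentq(outer_resid, 0.0, l1_total, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    f0 = _free_l0_given_l1(l0_total, f1, sites, l0_name, l1_name)

    bound: dict[tuple[str, str], float] = {}
    occ_num: dict[str, float] = {}
    occ_den: dict[str, float] = {}
    for pop in sites:
        b = _bound_at({l0_name: f0, l1_name: f1}, pop)
        for lig, v in b.items():
            key = (lig, pop.site_class)
            bound[key] = bound.get(key, 0.0) + v
        occ_den[pop.site_class] = occ_den.get(pop.site_class, 0.0) + pop.concentration
        occ_num[pop.site_class] = occ_num.get(pop.site_class, 0.0) + sum(b.values())
    occupancy = {
        cls: (occ_num.get(cls, 0.0) / den if den > 0 else 0.0)
        for cls, den in occ_den.items()
    }

    state = SpeciesState(free_l0=f0, free_l1=f1, bound=bound, occupancy=occupancy)
    _check_conservation(state, l0_total, l1_total, l0_name, l1_name)
    return state


def _check_conservation(
    state: SpeciesState, l0_total: float, l1_total: float, l0: str, l1: str
) -> None:
    r0 = abs(state.free_l0 + state.total_bound(l0) - l0_total) / max(l0_total, 1.0)
    r1 = abs(state.free_l1 + state.total_bound(l1) - l1_total) / max(l1_total, 1.0)
    if r0 > MASS_BALANCE_RTOL or r1 > MASS_BALANCE_RTOL:
        raise EquilibriumError(
            f"mass balance violated (residuals {r0:.2e}, {r1:.2e})", residuals=(r0, r1)
        )


def predict_intensity(
    state: SpeciesState, ligands: Iterable[LigandDef], l0_name: str | None = None
) -> float:
    """Total fluorescence of a solved state.

    Only reporter ligands contribute:
    ``F = brightness_bound * bound(all site classes) + brightness_free * free``.
    Dark competitors contribute nothing.
    """
    f = 0.0
    for lig in ligands:
        if lig.role != "reporter" or lig.signal_mode == "dark":
            continue
        free = state.free_l0 if (l0_name is None or lig.name == l0_name) else state.free_l1
        f += lig.brightness_bound * state.total_bound(lig.name) + lig.brightness_free * free
    return f


def predict_anisotropy(state: SpeciesState, ligand: LigandDef) -> float:
    """Observed anisotropy of the reporter under equal quantum yields.

    ``r = r_free + (r_bound - r_free) * f_bound`` with
    ``f_bound = bound / (bound + free)``.
    """
    if ligand.signal_mode != "anisotropy":
        raise EquilibriumError(f"ligand {ligand.name!r} is not an anisotropy reporter")
    bound = state.total_bound(ligand.name)
    free = state.free_l0
    total = bound + free
    if total <= 0:
        raise EquilibriumError("anisotropy undefined: no ligand present")
    f_bound = bound / total
    return ligand.r_free + (ligand.r_bound - ligand.r_free) * f_bound
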