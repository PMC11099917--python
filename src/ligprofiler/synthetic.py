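"""Synthetic titration generator with a ground-truth eight-polymorph panel.

The reference panel encodes eight fibril models (five de novo polymorphs
F, R, f65, f91, f110 and three PMCA-amplified patient-derived polymorphs
PD, MSA, DLB) whose simulated assays reproduce the qualitative ligand
profile of the study system:

* AAR binds every polymorph except R and f91;
* S5H displaces ThT only from f91, PD, MSA and DLB;
* BTA displaces ThT from every polymorph except F and R;
* OXI displaces ThT from all eight, but the shared-site fraction %BS1
  is low for R and f110 and high otherwise, with f65 > f110;
* S5H binds PD much more tightly than MSA or DLB;
* AAR binds MSA much more tightly than PD or DLB.

Absolute K_d values are not constrained by the study system, only
binding calls and orderings; the generator draws K_ds from plausible
sub-micromolar to micromolar ranges around documented nominal values,
jittered per seed while preserving every ordinal constraint.

Each fibril carries two site populations with a common reporter K_d:
BS1 (accessible to the reporter and to competitors) and BS2 (reporter
only), so the ground-truth %BS1 equals the BS1 share of bound reporter.
Concentrations are in nM; fibril concentrations are monomer-equivalent
with a default density of 0.2 reporter sites per monomer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .assays import CANDIDATE_ASSAYS, DEFAULT_ASSAYS, PROTOCOL_ASSAYS, AssayDef
from .equilibrium import (
    BS1,
    BS2,
    FibrilModel,
    LigandDef,
    SitePopulation,
    predict_anisotropy,
    predict_intensity,
    solve_competition_equilibrium,
)
from .isotherm import TitrationCurve

__all__ = [
    "NoiseModel",
    "AssaySpec",
    "PanelSpec",
    "REFERENCE_FIBRILS",
    "make_reference_panel",
    "simulate_assay",
    "simulate_panel",
    "titration_grid",
    "ground_truth_percent_bs1",
]

REFERENCE_FIBRILS = ("F", "R", "f65", "f91", "f110", "PD", "MSA", "DLB")

#: dark competitor-only ligands (must never access BS2)
DARK_COMPETITORS = frozenset({"S5H", "OXI", "ThR", "BTA"})

# nominal ground truth: BS1 fraction of reporter sites, and K_d (nM) per ligand
# (None = no binding).  Orderings, not magnitudes, are the constrained facts.
_BS1_FRAC = {"F": 0.88, "R": 0.35, "f65": 0.90, "f91": 0.92,
             "f110": 0.42, "PD": 0.90, "MSA": 0.86, "DLB": 0.93}
_KD_NOMINAL = {
    "ThT": {"F": 800, "R": 1000, "f65": 900, "f91": 1100,
            "f110": 950, "PD": 850, "MSA": 1050, "DLB": 900},
    "AAR": {"F": 600, "R": None, "f65": 800, "f91": None,
            "f110": 1200, "PD": 1000, "MSA": 250, "DLB": 2500},
    "S5H": {"F": None, "R": None, "f65": None, "f91": 900,
            "f110": None, "PD": 300, "MSA": 1500, "DLB": 2200},
    "BTA": {"F": None, "R": None, "f65": 700, "f91": 900,
            "f110": 1100, "PD": 1300, "MSA": 800, "DLB": 1500},
    "OXI": {"F": 500, "R": 600, "f65": 700, "f91": 800,
            "f110": 900, "PD": 1000, "MSA": 1100, "DLB": 450},
    "ThR": {f: 1000 for f in REFERENCE_FIBRILS},
}
#: ligands that also occupy the reporter-only class BS2
_BINDS_BS2 = frozenset({"ThT", "AAR"})

_LIGANDS = {
    "ThT": LigandDef("ThT", role="reporter", signal_mode="intensity",
                     brightness_free=0.002, brightness_bound=1.0),
    "AAR": LigandDef("AAR", role="reporter", signal_mode="intensity",
                     brightness_free=0.01, brightness_bound=1.2),
    "BTA": LigandDef("BTA", role="reporter", signal_mode="anisotropy",
                     r_free=0.05, r_bound=0.25),
    "S5H": LigandDef("S5H", role="competitor", signal_mode="dark"),
    "OXI": LigandDef("OXI", role="competitor", signal_mode="dark"),
    "ThR": LigandDef("ThR", role="competitor", signal_mode="dark"),
}


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian plate-reader noise: y = f * (1 + N(0, sigma_rel)) + N(0, sigma_abs)."""

    sigma_rel: float = 0.02
    sigma_abs: float = 0.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0 or self.sigma_abs < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class AssaySpec:
    """One assay of the panel: registry entry, fixed concs, titrant grid."""

    definition: AssayDef
    fixed_concs: Mapping[str, float]
    titrant: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "titrant", np.asarray(self.titrant, dtype=float))
        positive = self.titrant[self.titrant > 0]
        if len(positive) < 8:
            raise ValueError("assay grid needs >= 8 positive log-spaced points")

    @property
    def assay_id(self) -> str:
        return self.definition.assay_id


@dataclass(frozen=True)
class PanelSpec:
    """Eight-fibril ground truth plus the assays to run against it."""

    fibrils: tuple[FibrilModel, ...]
    assays: tuple[AssaySpec, ...]
    ligands: Mapping[str, LigandDef]
    ground_truth: Mapping[str, dict]
    seed: int

    def fibril(self, name: str) -> FibrilModel:
        for f in self.fibrils:
            if f.name == name:
                return f
        raise KeyError(f"unknown fibril {name!r}")

    def assay(self, assay_id: str) -> AssaySpec:
        for a in self.assays:
            if a.assay_id == assay_id:
                return a
        raise KeyError(f"unknown assay {assay_id!r}")

    def ground_truth_json(self) -> str:
        payload = {"seed": self.seed, "fibrils": self.ground_truth}
        return json.dumps(payload, indent=2, sort_keys=True)


def titration_grid(kd: float, n: int = 12, span: float = 30.0) -> np.ndarray:
    """Log-spaced titrant grid from kd/span to kd*span (identifiable by design)."""
    return np.geomspace(kd / span, kd * span, n)


def _draw_kds(rng: np.random.Generator) -> tuple[dict, dict]:
    """Per-seed jitter of the nominal truth, preserving all orderings."""
    kds: dict[str, dict[str, float | None]] = {}
    for lig in sorted(_KD_NOMINAL):
        kds[lig] = {}
        for fib in REFERENCE_FIBRILS:
            nominal = _KD_NOMINAL[lig][fib]
            if nominal is None:
                kds[lig][fib] = None
            else:
                kds[lig][fib] = float(nominal * np.exp(rng.uniform(-0.15, 0.15)))
    bs1 = {
        fib: float(np.clip(_BS1_FRAC[fib] + rng.uniform(-0.03, 0.03), 0.05, 0.97))
        for fib in REFERENCE_FIBRILS
    }
    return kds, bs1


def _build_fibril(name: str, kds: dict, bs1_frac: dict, total_sites: float) -> FibrilModel:
    c1 = bs1_frac[name] * total_sites
    c2 = total_sites - c1
    kd1 = {lig: kds[lig][name] for lig in kds if kds[lig][name] is not None}
    kd2 = {lig: kds[lig][name] for lig in _BINDS_BS2 if kds[lig][name] is not None}
    model = FibrilModel(name, (SitePopulation(BS1, c1, kd1), SitePopulation(BS2, c2, kd2)))
    model.validate_competitor_exclusion(DARK_COMPETITORS)
    return model


def make_reference_panel(
    seed: int,
    fibril_conc: float = 500.0,
    reporter_conc: float = 1000.0,
    sites_per_monomer: float = 0.2,
    extended: bool = False,
) -> PanelSpec:
    """Ground-truth eight-fibril panel reproducing the reference ligand profile.

    The same seed returns an identical panel; different seeds redraw the
    K_d magnitudes within their documented ranges while preserving every
    qualitative binding call and ordering.  ``extended=True`` adds the
    confirmatory ThT/ThR, AAR/ThT and BTA-direct assays to the four
    protocol assays.
    """
    rng = np.random.default_rng(seed)
    kds, bs1_frac = _draw_kds(rng)
    total_sites = sites_per_monomer * fibril_conc
    fibrils = tuple(
        _build_fibril(name, kds, bs1_frac, total_sites) for name in REFERENCE_FIBRILS
    )

    assay_ids = list(PROTOCOL_ASSAYS)
    if extended:
        assay_ids += [a for a in CANDIDATE_ASSAYS if a not in assay_ids]
        assay_ids.append("BTA-direct")
    direct_grid = np.geomspace(10.0, 6.0e4, 12)  # site-equivalent nM
    competition_grid = np.concatenate([[0.0], np.geomspace(30.0, 1.0e5, 11)])
    specs = []
    for aid in assay_ids:
        adef = DEFAULT_ASSAYS[aid]
        if adef.kind == "competition":
            specs.append(
                AssaySpec(adef, {"fibril": fibril_conc, "reporter": reporter_conc},
                          competition_grid)
            )
        elif adef.kind == "direct_intensity":
            specs.append(
                AssaySpec(adef, {"fibril": 0.0, "reporter": reporter_conc}, direct_grid)
            )
        else:  # direct anisotropy: dilute tracer, fibril titrated
            specs.append(AssaySpec(adef, {"fibril": 0.0, "reporter": 100.0}, direct_grid))

    truth = {}
    for fib in fibrils:
        entry = {
            "bs1_fraction": bs1_frac[fib.name],
            "kd_nM": {lig: kds[lig][fib.name] for lig in sorted(kds)},
            "sites_nM": [
                {"site_class": p.site_class, "concentration": p.concentration}
                for p in fib.sites
            ],
            "percent_bs1": {},
        }
        for spec in specs:
            adef = spec.definition
            if adef.kind != "competition":
                continue
            entry["percent_bs1"][adef.assay_id] = ground_truth_percent_bs1(
                fib, adef.reporter, adef.competitor, spec.fixed_concs["reporter"]
            )
        truth[fib.name] = entry

    return PanelSpec(
        fibrils=fibrils,
        assays=tuple(specs),
        ligands=dict(_LIGANDS),
        ground_truth=truth,
        seed=seed,
    )


def ground_truth_percent_bs1(
    model: FibrilModel, reporter: str, competitor: str, reporter_conc: float
) -> float:
    """BS1 share of bound reporter at zero competitor, from the exact equilibrium.

    This is the limiting fraction of reporter signal lost on complete
    displacement under equal bound-state brightness.
    """
    state = solve_competition_equilibrium(
        reporter_conc, 0.0, model.sites, l0_name=reporter, l1_name=competitor or "_none"
    )
    shared = sum(
        v for (lig, cls), v in state.bound.items()
        if lig == reporter and any(
            p.site_class == cls and p.binds(competitor) for p in model.sites
        )
    )
    total = state.total_bound(reporter)
    if total <= 0:
        return float("nan")
    return 100.0 * shared / total


def _forward_signal(
    model: FibrilModel, spec: AssaySpec, ligands: Mapping[str, LigandDef]
) -> np.ndarray:
    """Noise-free predicted signal over the assay's titrant grid."""
    adef = spec.definition
    reporter = ligands[adef.reporter]
    l_tot = spec.fixed_concs["reporter"]
    out = np.empty(len(spec.titrant))
    if adef.kind == "competition":
        for i, l1 in enumerate(spec.titrant):
            state = solve_competition_equilibrium(
                l_tot, l1, model.sites, l0_name=adef.reporter, l1_name=adef.competitor
            )
            out[i] = predict_intensity(state, [reporter], l0_name=adef.reporter)
        return out
    # direct titration: fibril sites added to fixed reporter
    total_sites = model.total_sites(adef.reporter)
    for i, s in enumerate(spec.titrant):
        if total_sites > 0:
            scale = s / total_sites
            scaled = [replace(p, concentration=p.concentration * scale) for p in model.sites]
        else:
            scaled = [replace(p, concentration=0.0) for p in model.sites]
        state = solve_competition_equilibrium(
            l_tot, 0.0, scaled, l0_name=adef.reporter, l1_name="_none"
        )
        if adef.kind == "direct_anisotropy":
            out[i] = predict_anisotropy(state, reporter)
        else:
            out[i] = predict_intensity(state, [reporter], l0_name=adef.reporter)
    return out


def _blank_signal(spec: AssaySpec, ligands: Mapping[str, LigandDef]) -> float:
    """Reporter signal with no fibril (the measured background)."""
    reporter = ligands[spec.definition.reporter]
    if reporter.signal_mode == "anisotropy":
        return reporter.r_free
    return reporter.brightness_free * spec.fixed_concs["reporter"]


def simulate_assay(
    panel: PanelSpec, fibril: str, assay_id: str, noise: NoiseModel
) -> list[TitrationCurve]:
    """Simulate one assay on one fibril: one noisy curve per replicate.

    The random stream is keyed on (seed, fibril index, assay index,
    replicate), so any subset of the panel reproduces bit-for-bit.
    """
    model = panel.fibril(fibril)
    spec = panel.assay(assay_id)
    fib_idx = [f.name for f in panel.fibrils].index(fibril)
    assay_idx = [a.assay_id for a in panel.assays].index(assay_id)
    clean = _forward_signal(model, spec, panel.ligands)
    blank = _blank_signal(spec, panel.ligands)
    adef = spec.definition
    curves = []
    for rep in range(noise.replicates):
        rng = np.random.default_rng([noise.seed, fib_idx, assay_idx, rep])
        y = clean * (1.0 + rng.normal(0.0, noise.sigma_rel, clean.shape))
        y = y + rng.normal(0.0, noise.sigma_abs, clean.shape)
        curves.append(
            TitrationCurve(
                assay_kind=adef.kind,
                reporter=adef.reporter,
                competitor=adef.competitor,
                fixed_concs=dict(spec.fixed_concs),
                titrant_conc=spec.titrant.copy(),
                signal=y,
                replicate_id=f"r{rep + 1}",
                assay_id=adef.assay_id,
                fibril=fibril,
                background=blank,
            )
        )
    return curves


def simulate_panel(panel: PanelSpec, noise: NoiseModel) -> list[TitrationCurve]:
    """Simulate every (assay, fibril) combination of the panel."""
    curves: list[TitrationCurve] = []
    for spec in panel.assays:
        for fib in panel.fibrils:
            curves.extend(simulate_assay(panel, fib.name, spec.assay_id, noise))
    return curves
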