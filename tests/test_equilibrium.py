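"""Exact-solution properties of the binding equilibrium solvers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligprofiler import (
    EquilibriumError,
    FibrilModel,
    LigandDef,
    SitePopulation,
    predict_anisotropy,
    predict_intensity,
    solve_binary_equilibrium,
    solve_competition_equilibrium,
)
from ligprofiler.equilibrium import BS1, BS2


def bisect_binary(l_total, s_total, kd, iters=200):
    """Independent oracle: bisection on the mass-balance residual."""
    if l_total == 0 or s_total == 0:
        return 0.0
    lo, hi = 0.0, min(l_total, s_total)

    def resid(b):
        return b * b - (l_total + s_total + kd) * b + l_total * s_total

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if resid(mid) > 0:  # resid is positive below the physical root
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestBinaryEquilibrium:
    @pytest.mark.parametrize(
        "l_total,s_total,kd,expected,tol",
        [
            (0.0, 500.0, 100.0, 0.0, 0.0),
            (1000.0, 500.0, 1e-9, 500.0, 1e-6),
            # closed form 50*(3 - sqrt(5)); cross-checked by bisection below
            (100.0, 100.0, 100.0, 38.1966, 1e-4),
        ],
    )
    def test_known_solutions(self, l_total, s_total, kd, expected, tol):
        b = solve_binary_equilibrium(l_total, s_total, kd)
        assert b == pytest.approx(expected, abs=max(tol, 1e-12), rel=tol or None)

    def test_negative_inputs_rejected(self):
        with pytest.raises(EquilibriumError):
            solve_binary_equilibrium(-1.0, 10.0, 1.0)
        with pytest.raises(EquilibriumError):
            solve_binary_equilibrium(1.0, 10.0, 0.0)

    def test_agrees_with_bisection_over_log_grid(self):
        grid = np.geomspace(1e-3, 1e6, 7)
        for l in grid:
            for s in grid:
                for kd in grid:
                    b = solve_binary_equilibrium(l, s, kd)
                    oracle = bisect_binary(l, s, kd)
                    assert b == pytest.approx(oracle, rel=1e-9, abs=1e-12)
                    assert 0.0 <= b <= min(l, s) + 1e-12

    @given(
        l=st.floats(1e-3, 1e6),
        s=st.floats(1e-3, 1e6),
        kd=st.floats(1e-3, 1e6),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_mass_balance_and_bounds(self, l, s, kd):
        b = solve_binary_equilibrium(l, s, kd)
        free_l, free_s = l - b, s - b
        assert free_l >= -1e-9 * l and free_s >= -1e-9 * s
        # the root satisfies b*Kd = free_l * free_s (law of mass action)
        assert b * kd == pytest.approx(free_l * free_s, rel=1e-6, abs=1e-9)


def two_site_sites(c1=100.0, c2=100.0, kd0_1=500.0, kd0_2=500.0, kd1_1=200.0):
    return (
        SitePopulation(BS1, c1, {"L0": kd0_1, "L1": kd1_1}),
        SitePopulation(BS2, c2, {"L0": kd0_2}),
    )


def brute_force_free_l0(l0_total, sites, iters=200):
    """1-D bisection oracle on free L0 for the competitor-free system."""
    def resid(f0):
        b = sum(
            p.concentration * (f0 / p.kd["L0"]) / (1 + f0 / p.kd["L0"])
            for p in sites
            if "L0" in p.kd
        )
        return f0 + b - l0_total

    lo, hi = 0.0, l0_total
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if resid(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestCompetitionEquilibrium:
    def test_reduces_to_binary_without_competitor(self):
        sites = (SitePopulation(BS1, 250.0, {"L0": 700.0, "L1": 100.0}),)
        state = solve_competition_equilibrium(1000.0, 0.0, sites)
        assert state.total_bound("L0") == pytest.approx(
            solve_binary_equilibrium(1000.0, 250.0, 700.0), rel=1e-9
        )

    def test_two_site_matches_brute_force(self):
        sites = two_site_sites(kd0_1=300.0, kd0_2=900.0)
        state = solve_competition_equilibrium(1000.0, 0.0, sites)
        f0 = brute_force_free_l0(1000.0, sites)
        assert state.free_l0 == pytest.approx(f0, rel=1e-8)

    def test_complete_displacement_limit(self):
        # large reporter excess so that freed L0 cannot shift BS2 occupancy
        sites = two_site_sites(c1=100.0, c2=100.0)
        before = solve_competition_equilibrium(1e6, 0.0, sites)
        after = solve_competition_equilibrium(1e6, 1e9, sites)
        assert after.bound[("L0", BS1)] < 1e-3 * before.bound[("L0", BS1)]
        assert after.bound[("L0", BS2)] == pytest.approx(
            before.bound[("L0", BS2)], rel=1e-6
        )

    def test_symmetric_sites_split_equally(self):
        sites = (
            SitePopulation(BS1, 100.0, {"L0": 500.0, "L1": 100.0}),
            SitePopulation(BS1, 100.0, {"L0": 500.0, "ghost": 1.0}),
        )
        state = solve_competition_equilibrium(400.0, 0.0, sites)
        per_pop = state.bound[("L0", BS1)]
        single = solve_binary_equilibrium(400.0, 200.0, 500.0)
        assert per_pop == pytest.approx(single, rel=1e-9)

    def test_bound_l0_monotone_in_competitor(self):
        sites = two_site_sites()
        l1_grid = np.geomspace(1.0, 1e6, 25)
        bs1_bound = [
            solve_competition_equilibrium(1000.0, l1, sites).bound[("L0", BS1)]
            for l1 in l1_grid
        ]
        assert all(b2 <= b1 + 1e-9 for b1, b2 in zip(bs1_bound, bs1_bound[1:]))

    def test_intensity_monotone_when_free_is_dark(self):
        sites = two_site_sites()
        tht = LigandDef("L0", brightness_free=0.0, brightness_bound=1.0)
        f = [
            predict_intensity(
                solve_competition_equilibrium(1000.0, l1, sites), [tht]
            )
            for l1 in np.geomspace(1.0, 1e6, 25)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(f, f[1:]))

    def test_mass_conservation_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            c1, c2, l0, l1 = 10.0 ** rng.uniform(-1, 4, 4)
            kds = 10.0 ** rng.uniform(0, 4, 3)
            sites = (
                SitePopulation(BS1, c1, {"L0": kds[0], "L1": kds[1]}),
                SitePopulation(BS2, c2, {"L0": kds[2]}),
            )
            state = solve_competition_equilibrium(l0, l1, sites)
            assert state.free_l0 + state.total_bound("L0") == pytest.approx(
                l0, rel=1e-8, abs=1e-8
            )
            assert state.free_l1 + state.total_bound("L1") == pytest.approx(
                l1, rel=1e-8, abs=1e-8
            )
            for cls, occ in state.occupancy.items():
                assert 0.0 <= occ <= 1.0 + 1e-12

    def test_endpoint_identity_equal_brightness(self):
        # fraction of signal lost on full displacement = BS1 share at l1=0
        sites = two_site_sites(c1=80.0, c2=120.0)
        tht = LigandDef("L0", brightness_free=0.0, brightness_bound=1.0)
        start = solve_competition_equilibrium(1e5, 0.0, sites)
        end = solve_competition_equilibrium(1e5, 1e10, sites)
        f_start = predict_intensity(start, [tht])
        f_end = predict_intensity(end, [tht])
        share = start.bound[("L0", BS1)] / start.total_bound("L0")
        assert (f_start - f_end) / f_start == pytest.approx(share, abs=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(EquilibriumError):
            solve_competition_equilibrium(-1.0, 0.0, two_site_sites())
        with pytest.raises(EquilibriumError):
            solve_competition_equilibrium(1.0, 0.0, ())


class TestSignals:
    def test_intensity_zero_when_dark(self):
        sites = (SitePopulation(BS1, 10.0, {"L0": 1e9}),)
        state = solve_competition_equilibrium(100.0, 0.0, sites)
        lig = LigandDef("L0", brightness_free=0.0, brightness_bound=5.0)
        assert predict_intensity(state, [lig]) == pytest.approx(
            5.0 * state.total_bound("L0")
        )
        dark = LigandDef("L1", role="competitor", signal_mode="dark")
        assert predict_intensity(state, [dark]) == 0.0

    def test_intensity_arithmetic(self):
        sites = (SitePopulation(BS1, 10.0, {"L0": 1e-7}),)
        state = solve_competition_equilibrium(1e4, 0.0, sites)
        lig = LigandDef("L0", brightness_free=0.0, brightness_bound=5.0)
        # all 10 nM of sites occupied at 5 units/nM
        assert predict_intensity(state, [lig]) == pytest.approx(50.0, rel=1e-6)

    @pytest.mark.parametrize(
        "l_total,sites_conc,expected",
        [(100.0, 0.0, 0.05), (100.0, 1e9, 0.25)],
    )
    def test_anisotropy_limits(self, l_total, sites_conc, expected):
        lig = LigandDef("BTA", signal_mode="anisotropy", r_free=0.05, r_bound=0.25)
        sites = (SitePopulation(BS1, sites_conc, {"BTA": 1.0}),)
        state = solve_competition_equilibrium(
            l_total, 0.0, sites, l0_name="BTA"
        )
        assert predict_anisotropy(state, lig) == pytest.approx(expected, abs=1e-4)

    def test_anisotropy_midpoint_arithmetic(self):
        from ligprofiler.equilibrium import SpeciesState

        lig = LigandDef("BTA", signal_mode="anisotropy", r_free=0.05, r_bound=0.25)
        state = SpeciesState(
            free_l0=5.0, free_l1=0.0, bound={("BTA", BS1): 5.0}, occupancy={BS1: 0.5}
        )
        assert predict_anisotropy(state, lig) == pytest.approx(0.15)

    def test_anisotropy_undefined_without_ligand(self):
        from ligprofiler.equilibrium import SpeciesState

        lig = LigandDef("BTA", signal_mode="anisotropy")
        empty = SpeciesState(free_l0=0.0, free_l1=0.0, bound={}, occupancy={})
        with pytest.raises(EquilibriumError):
            predict_anisotropy(empty, lig)


class TestDomainTypes:
    def test_ligand_validation(self):
        with pytest.raises(EquilibriumError):
            LigandDef("x", role="bystander")
        with pytest.raises(EquilibriumError):
            LigandDef("x", brightness_bound=-1.0)
        with pytest.raises(EquilibriumError):
            LigandDef("x", signal_mode="intensity", brightness_free=2.0, brightness_bound=1.0)
        with pytest.raises(EquilibriumError):
            LigandDef("x", signal_mode="anisotropy", r_free=0.3, r_bound=0.2)

    def test_site_validation(self):
        with pytest.raises(EquilibriumError):
            SitePopulation(BS1, -5.0)
        with pytest.raises(EquilibriumError):
            SitePopulation(BS1, 5.0, {"L0": 0.0})
        with pytest.raises(EquilibriumError):
            SitePopulation("BS3", 5.0)

    def test_fibril_validation(self):
        pop = SitePopulation(BS1, 5.0, {"ThT": 100.0})
        with pytest.raises(EquilibriumError):
            FibrilModel("dup", (pop, pop))
        bad = FibrilModel(
            "leaky", (SitePopulation(BS2, 5.0, {"ThT": 100.0, "OXI": 10.0}),)
        )
        with pytest.raises(EquilibriumError):
            bad.validate_competitor_exclusion({"OXI"})
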