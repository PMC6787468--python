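"""Competitive equilibrium solver, Cheng-Prusoff conversions, wash kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msbind import (
    AssayConfig,
    KineticSpec,
    LigandSite,
    ic50_from_ki,
    ki_from_ic50,
    koff_from_kd,
    reporter_remaining_pct,
    solve_equilibrium,
    wash_retention,
)
from msbind.errors import InputError, UndefinedRatioError

from conftest import grid_solve_tfree

REPORTER = LigandSite("NO711", 10.0, 23.6)


class TestSolveEquilibrium:
    def test_no_ligands_identity(self):
        state = solve_equilibrium(3.0, [])
        assert state.free_target == 3.0
        assert state.ligands == ()

    def test_single_competitor_bound_matches_printed_estimate(self):
        # one 1 uM component at the 50%-inhibition affinity binds ~1.5 nM of
        # a 3 nM target alongside the 10 nM reporter
        ki = ki_from_ic50(1000.0, 10.0, 23.6)
        state = solve_equilibrium(3.0, [REPORTER, LigandSite("inh", 1000.0, ki)])
        assert round(state.bound("inh"), 1) == 1.5

    def test_two_equal_competitors_split_the_target(self):
        ki = ki_from_ic50(1000.0, 10.0, 23.6)
        state = solve_equilibrium(
            3.0,
            [REPORTER, LigandSite("a", 1000.0, ki), LigandSite("b", 1000.0, ki)],
        )
        assert round(state.bound("a"), 1) == 1.0
        assert round(state.bound("b"), 1) == 1.0

    def test_weak_binder_suppressed_to_30_pM_by_strong_binder(self):
        ki = ki_from_ic50(1000.0, 10.0, 23.6)
        state = solve_equilibrium(
            3.0,
            [
                REPORTER,
                LigandSite("weak", 1000.0, ki),
                LigandSite("strong", 1000.0, ki / 100.0),
            ],
        )
        assert state.bound("weak") == pytest.approx(0.03, abs=0.005)

    @given(
        target=st.floats(0.1, 100.0),
        lconc=st.floats(0.0, 1e4),
        kd=st.floats(0.5, 1e4),
    )
    @settings(max_examples=100, deadline=None)
    def test_single_ligand_matches_closed_form_quadratic(self, target, lconc, kd):
        # one site with depletion has the quadratic solution
        # T^2 + (Kd + L - T_tot) T - T_tot Kd = 0
        b = kd + lconc - target
        t_free = 0.5 * (-b + math.sqrt(b * b + 4.0 * target * kd))
        state = solve_equilibrium(target, [LigandSite("L", lconc, kd)])
        assert state.free_target == pytest.approx(t_free, rel=1e-9, abs=1e-12)

    @given(
        target=st.floats(0.01, 50.0),
        concs=st.lists(st.floats(0.0, 5e3), min_size=1, max_size=4),
        kds=st.lists(st.floats(0.5, 5e3), min_size=4, max_size=4),
    )
    @settings(max_examples=60, deadline=None)
    def test_conservation_holds(self, target, concs, kds):
        ligands = [
            LigandSite(f"L{i}", c, kds[i]) for i, c in enumerate(concs)
        ]
        state = solve_equilibrium(target, ligands)
        assert state.residual <= 1e-9 * max(1.0, target)
        for lig, solved in zip(ligands, state.ligands):
            assert solved.free_conc + solved.bound_conc == pytest.approx(
                lig.total_conc, rel=1e-9, abs=1e-9
            )
            assert solved.free_conc >= 0 and solved.bound_conc >= 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 5)
        ligands = [
            LigandSite(f"L{i}", float(rng.uniform(1, 5e3)), float(rng.uniform(1, 2e3)))
            for i in range(n)
        ]
        target = float(rng.uniform(0.5, 30.0))
        t_oracle = grid_solve_tfree(target, ligands)
        state = solve_equilibrium(target, ligands)
        assert state.free_target == pytest.approx(t_oracle, rel=1e-6)

    def test_adding_competitor_never_raises_reporter_binding(self):
        base = solve_equilibrium(3.0, [REPORTER]).bound("NO711")
        prev = base
        for conc in [10.0, 100.0, 1000.0, 1e4, 1e6]:
            bound = solve_equilibrium(
                3.0, [REPORTER, LigandSite("c", conc, 500.0)]
            ).bound("NO711")
            assert bound <= prev + 1e-12
            prev = bound

    def test_non_depleting_limit_matches_fractional_occupancy(self):
        ligands = [REPORTER, LigandSite("c", 800.0, 300.0)]
        state = solve_equilibrium(1e-8, ligands)
        denom = 1.0 + 10.0 / 23.6 + 800.0 / 300.0
        for lig in ligands:
            expected = (lig.total_conc / lig.kd) / denom
            assert state.bound(lig.ligand_id) / 1e-8 == pytest.approx(
                expected, rel=1e-4
            )

    def test_zero_concentration_ligand_contributes_nothing(self):
        state = solve_equilibrium(3.0, [REPORTER, LigandSite("ghost", 0.0, 5.0)])
        ref = solve_equilibrium(3.0, [REPORTER])
        assert state.free_target == pytest.approx(ref.free_target, rel=1e-12)
        assert state.bound("ghost") == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):
            solve_equilibrium(-1.0, [])
        with pytest.raises(InputError):
            LigandSite("x", -5.0, 10.0)
        with pytest.raises(InputError):
            LigandSite("x", 5.0, 0.0)


class TestReporterRemaining:
    def test_no_competitors_is_100(self, config):
        assert reporter_remaining_pct(config, []) == pytest.approx(100.0)

    def test_ic50_strength_competitor_leaves_about_half(self, config):
        # with target depletion the exactly-IC50 competitor leaves ~51%
        pct = reporter_remaining_pct(config, [LigandSite("c", 1000.0, 700.0)])
        assert pct == pytest.approx(51.0, abs=1.0)

    def test_saturating_competitor_abolishes_binding(self, config):
        pct = reporter_remaining_pct(config, [LigandSite("c", 1e9, 700.0)])
        assert pct < 0.1

    def test_zero_target_is_undefined(self):
        from types import SimpleNamespace

        cfg = SimpleNamespace(reporter_conc=10.0, reporter_kd=23.6, target_conc=0.0)
        with pytest.raises(UndefinedRatioError):
            reporter_remaining_pct(cfg, [])

    def test_non_depleting_half_inhibition_at_cheng_prusoff_ic50(self):
        # as target -> 0, the concentration halving reporter binding converges
        # to IC50 = Ki (1 + [R]/Kd)
        cfg = AssayConfig(target_conc=1e-6)
        ki = 700.0
        ic50 = ic50_from_ki(ki, cfg.reporter_conc, cfg.reporter_kd)
        pct = reporter_remaining_pct(cfg, [LigandSite("c", ic50, ki)])
        assert pct == pytest.approx(50.0, rel=0.01)


class TestChengPrusoff:
    def test_printed_worked_value(self):
        ki = ki_from_ic50(1000.0, 10.0, 23.6)
        assert ki == pytest.approx(702.4, abs=0.05)
        assert round(ki, -2) == 700.0

    def test_zero_reporter_reduces_to_identity(self):
        assert ki_from_ic50(1000.0, 0.0, 23.6) == 1000.0

    @given(
        ic50=st.floats(1.0, 1e6),
        r=st.floats(0.0, 1e3),
        kd=st.floats(0.1, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, ic50, r, kd):
        assert ic50_from_ki(ki_from_ic50(ic50, r, kd), r, kd) == pytest.approx(
            ic50, rel=1e-12
        )

    def test_invalid(self):
        with pytest.raises(InputError):
            ki_from_ic50(0.0, 10.0, 23.6)
        with pytest.raises(InputError):
            ki_from_ic50(100.0, 10.0, -1.0)


class TestWashAndKinetics:
    def test_zero_time_full_retention(self):
        assert wash_retention(KineticSpec(1.5e-3), 0.0) == 1.0

    def test_reporter_loses_9pct_in_a_minute(self):
        assert wash_retention(KineticSpec(1.5e-3), 60.0) == pytest.approx(
            0.9139, abs=5e-5
        )

    def test_monotone_in_time_and_rate(self):
        times = [0.0, 10.0, 30.0, 120.0]
        vals = [wash_retention(KineticSpec(1.5e-3), t) for t in times]
        assert vals == sorted(vals, reverse=True)
        rates = [1e-4, 1e-3, 1e-2]
        vals = [wash_retention(KineticSpec(k), 60.0) for k in rates]
        assert vals == sorted(vals, reverse=True)

    def test_negative_time_rejected(self):
        with pytest.raises(InputError):
            wash_retention(KineticSpec(1.5e-3), -1.0)

    def test_koff_from_reporter_constants(self):
        # the reporter's printed Kd and koff are mutually consistent with
        # kon ~ 6.36e4 M^-1 s^-1
        assert koff_from_kd(23.6, 6.36e4) == pytest.approx(1.5e-3, rel=0.01)

    def test_koff_scales_linearly_in_kon(self):
        assert koff_from_kd(23.6, 2 * 6.36e4) == pytest.approx(
            2 * koff_from_kd(23.6, 6.36e4)
        )

    def test_koff_invalid(self):
        with pytest.raises(InputError):
            koff_from_kd(0.0, 6.4e4)
        with pytest.raises(InputError):
            koff_from_kd(23.6, 0.0)

    def test_kinetic_spec_consistency_check(self):
        spec = KineticSpec(koff=1.5e-3, kon=6.36e4)
        spec.check_kd(23.6)  # consistent within 1%
        with pytest.raises(InputError):
            spec.check_kd(50.0)
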