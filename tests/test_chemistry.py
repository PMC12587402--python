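"""Speciation, pH solving, inverse titration and design-space decoding."""

import numpy as np
import pytest
from scipy.optimize import brentq

from formubo import chemistry as ch
from formubo.chemistry import (
    DesignSpace,
    InfeasibleTargetError,
    UnknownComponentError,
    acid_totals_for_target_pH,
    check_feasibility,
    decode_point,
    estimate_osmolality,
    solve_mixture_pH,
    speciate,
)

KW = 1e-14


def oracle_pH_bisection(charge_fn, lo=0.0, hi=14.0, steps=200):
    """Independent bisection on an explicit charge-balance callable."""
    for _ in range(steps):
        mid = 0.5 * (lo + hi)
        if charge_fn(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestForwardSolver:
    def test_strong_acid_limit(self):
        assert solve_mixture_pH({"chloride": 1.0}) == pytest.approx(3.00, abs=0.01)

    def test_weak_acid_vs_bisection_oracle(self):
        # 10 mM acetic acid, pKa 4.76: charge balance H - Kw/H - c*Ka/(Ka+H)
        ka = 10**-4.76
        c = 0.010

        def charge(pH):
            h = 10**-pH
            return h - KW / h - c * ka / (ka + h)

        expected = oracle_pH_bisection(charge)
        assert expected == pytest.approx(3.39, abs=0.01)
        assert solve_mixture_pH({"acetic": 10.0}) == pytest.approx(expected, abs=1e-6)

    def test_pure_water(self):
        assert solve_mixture_pH({}) == pytest.approx(7.00, abs=1e-9)

    def test_unknown_component_raises(self):
        with pytest.raises(UnknownComponentError):
            solve_mixture_pH({"unobtainium": 1.0})

    def test_negative_concentration_raises(self):
        with pytest.raises(ValueError):
            solve_mixture_pH({"acetic": -1.0})

    def test_monotone_in_acid_total(self):
        phs = [
            solve_mixture_pH({"histidine": 10.0, "chloride": c})
            for c in np.linspace(0.0, 30.0, 12)
        ]
        assert np.all(np.diff(phs) < 0)


class TestSpeciation:
    @pytest.mark.parametrize(
        "comp",
        [
            {"histidine": 10.0, "chloride": 5.0},
            {"histidine": 10.0, "arginine": 100.0, "aspartic": 20.0, "acetic": 15.0},
            {"glutamic": 8.0, "sorbitol": 300.0},
        ],
    )
    def test_electroneutrality_and_mass_balance(self, comp):
        table = speciate(comp)
        assert abs(table.charge_residual()) < 1e-10
        for name, rows in table.species.items():
            total = sum(c for _, c in rows)
            assert total == pytest.approx(comp[name], rel=1e-9, abs=1e-12)


class TestInverseSolver:
    def test_hcl_only_matches_forward(self):
        totals = acid_totals_for_target_pH(6.0, (0, 0, 1, 0), 10.0, 0.0)
        pH = solve_mixture_pH({"histidine": 10.0, "chloride": totals["hcl"]})
        assert pH == pytest.approx(6.0, abs=1e-4)

    def test_acetic_cannot_exceed_neutral(self):
        with pytest.raises(InfeasibleTargetError):
            acid_totals_for_target_pH(7.5, (0, 0, 0, 1), 0.0, 0.0)

    def test_matches_bisection_oracle_on_forward_solver(self):
        """Independent oracle: bisect the total acid C against the forward
        brentq pH solve until the target pH is met."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            f = rng.dirichlet(np.ones(4))
            target = rng.uniform(4.5, 7.0)
            arg = rng.uniform(0.0, 250.0)

            def ph_of_C(C):
                comp = {
                    "histidine": 10.0,
                    "arginine": arg,
                    "aspartic": C * f[0],
                    "glutamic": C * f[1],
                    "chloride": C * f[2],
                    "acetic": C * f[3],
                }
                return solve_mixture_pH(comp)

            try:
                totals = acid_totals_for_target_pH(
                    target, tuple(f), 10.0, arg
                )
            except InfeasibleTargetError:
                assert ph_of_C(0.0) < target or ph_of_C(2000.0) > target
                continue
            C_impl = sum(totals.values())
            lo, hi = 0.0, 2000.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if ph_of_C(mid) > target:
                    lo = mid
                else:
                    hi = mid
            assert C_impl == pytest.approx(0.5 * (lo + hi), abs=1e-6)

    def test_matches_fine_grid_search(self):
        """1 uM local grid around the solution brackets it within one step."""
        for target, arg in [(5.0, 0.0), (6.2, 120.0), (7.0, 30.0)]:
            totals = acid_totals_for_target_pH(target, (0.2, 0.2, 0.3, 0.3), 10.0, arg)
            C = sum(totals.values())
            grid = C + np.arange(-5, 6) * 1e-3  # 1 uM steps in mM units
            grid = grid[grid >= 0]
            phs = np.array(
                [
                    solve_mixture_pH(
                        {
                            "histidine": 10.0,
                            "arginine": arg,
                            "aspartic": 0.2 * g,
                            "glutamic": 0.2 * g,
                            "chloride": 0.3 * g,
                            "acetic": 0.3 * g,
                        }
                    )
                    for g in grid
                ]
            )
            best = grid[np.argmin(np.abs(phs - target))]
            assert abs(best - C) <= 1e-3 + 1e-9

    def test_bad_fractions_raise(self):
        with pytest.raises(ValueError):
            acid_totals_for_target_pH(6.0, (0.5, 0.5, 0.5, -0.5), 10.0, 0.0)


class TestOsmolality:
    def test_direct_sum(self):
        form = decode_point(np.zeros(6))  # placeholder; build explicitly below
        f = ch.Formulation(
            sorbitol=300.0, arginine=0.0, pH=5.0, f_asp=0, f_glu=0, f_hcl=1,
            f_acetic=0, acid_totals={"asp": 0, "glu": 0, "hcl": 5.0, "acetic": 0},
            histidine=10.0,
        )
        assert estimate_osmolality(f) == pytest.approx(315.0)

    def test_histidine_only(self):
        f = ch.Formulation(
            sorbitol=0, arginine=0, pH=7, f_asp=0, f_glu=0, f_hcl=0, f_acetic=1,
            acid_totals={"asp": 0, "glu": 0, "hcl": 0, "acetic": 0}, histidine=10.0,
        )
        assert estimate_osmolality(f) == pytest.approx(10.0)

    def test_sorbitol_linearity(self):
        u = np.array([0.4, 0.1, 0.5, 0.0, 0.0, 0.9])
        f1 = decode_point(u)
        space2 = DesignSpace()
        import dataclasses

        f2 = dataclasses.replace(f1, sorbitol=f1.sorbitol + 50.0)
        assert estimate_osmolality(f2) - estimate_osmolality(f1) == pytest.approx(50.0)


class TestDecode:
    def test_lower_bound_corner(self):
        f = decode_point(np.zeros(6))
        assert f.sorbitol == 0 and f.arginine == 0
        assert f.pH == pytest.approx(4.5)
        assert f.f_acetic == pytest.approx(1.0)

    def test_midpoint_affine(self):
        f = decode_point(np.array([0.5, 0.0, 0.5, 0.0, 0.0, 0.5]))
        assert f.sorbitol == pytest.approx(275.0)

    def test_fraction_simplex_violation(self):
        f = decode_point(np.array([0.5, 0.0, 0.5, 0.6, 0.5, 0.3]))
        assert not f.feasible
        assert "simplex" in f.reason

    def test_out_of_cube_raises(self):
        with pytest.raises(ValueError):
            decode_point(np.array([1.2, 0, 0, 0, 0, 0]))

    def test_minimal_acid_fails_osmolality_floor(self):
        # no sorbitol/arginine at pH 7.5: almost no acid needed -> ~10 mOsm/kg
        f = decode_point(np.array([0.0, 0.0, 1.0, 0.0, 0.0, 1.0]))
        assert not f.feasible
        assert "osmolality" in f.reason
        assert f.osmolality < 100

    def test_mid_sorbitol_hcl_point_is_feasible(self):
        u = np.array([300 / 550, 0.0, 0.5, 0.0, 0.0, 1.0])
        f = decode_point(u)
        assert f.feasible
        report = check_feasibility(f)
        assert report.feasible and report.violations == ()

    def test_forward_inverse_roundtrip_random_points(self):
        rng = np.random.default_rng(5)
        space = DesignSpace()
        checked = 0
        while checked < 100:
            u = rng.random(6)
            f = decode_point(u, space)
            if not f.feasible:
                continue
            pH = solve_mixture_pH(f.composition())
            assert abs(pH - f.pH) < 1e-4
            checked += 1


class TestDesignSpace:
    def test_invalid_ranges_raise(self):
        with pytest.raises(ValueError):
            DesignSpace(sorbitol_range=(100.0, 0.0))
        with pytest.raises(ValueError):
            DesignSpace(f_asp_range=(0.0, 1.5))
        with pytest.raises(ValueError):
            DesignSpace(histidine_fixed=0.0)
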