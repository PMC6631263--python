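"""Phase-diagram assembly, eutectic location, and depression metrics."""

import math

import numpy as np
import pytest

from desle import (
    BinarySystem,
    MeltingProperties,
    NoEutecticError,
    PositiveDeviationWarning,
    R,
    RKCoefficients,
    ThermoDomainError,
    eutectic_point,
    liquidus_curve,
    normalized_depression,
    phase_boundary_table,
)


def envelope_minimum_oracle(system, n=1_000_000):
    """Dense-grid upper-envelope-minimum oracle, computed from the closed
    form directly (independent of the bisection-based solver)."""
    x = np.unique(
        np.concatenate(
            [
                np.geomspace(1e-7, 0.05, n // 4),
                np.linspace(0.05, 0.95, n // 2),
                1 - np.geomspace(1e-7, 0.05, n // 4),
            ]
        )
    )

    def branch_T(x_cr, props, coeffs):
        P = np.zeros_like(x_cr)
        for k, c in enumerate(coeffs.coeffs):
            P += c * (1 - x_cr) ** (k + 2)
        num = props.dHm + P
        den = props.dHm / props.Tm - R * np.log(x_cr)
        return np.where(num > 0, num / den, np.nan)

    T1 = branch_T(x, system.props1, system.coeffs1)
    T2 = branch_T(1 - x, system.props2, system.coeffs2)
    env = np.fmax(T1, T2)
    i = np.nanargmin(env)
    return float(x[i]), float(env[i])


class TestEutecticPoint:
    def test_symmetric_ideal_system_is_equimolar(self, symmetric_system):
        eut = eutectic_point(symmetric_system)
        assert eut.x1_e == pytest.approx(0.5, abs=1e-9)
        assert eut.gamma1_e == 1.0 and eut.gamma2_e == 1.0

    def test_walden_ideal_eutectic_sits_near_pure_low_melter(self, walden_system):
        """Very dissimilar ideal pairs have their eutectic within ~1e-3 of
        the low-melting side, barely below its melting point."""
        eut = eutectic_point(walden_system)
        assert eut.x1_e < 0.01
        assert 299.0 < eut.Te < 300.0
        x_oracle, T_oracle = envelope_minimum_oracle(walden_system)
        assert eut.x1_e == pytest.approx(x_oracle, rel=1e-3)
        assert eut.Te == pytest.approx(T_oracle, abs=1e-4)

    def test_branches_agree_at_the_refined_eutectic(self, walden_system):
        from desle import branch_temperatures

        eut = eutectic_point(walden_system)
        T1 = float(branch_temperatures(walden_system, 1, eut.x1_e))
        T2 = float(branch_temperatures(walden_system, 2, eut.x1_e))
        assert abs(T1 - T2) <= 1e-8

    def test_component1_nonideality_deepens_and_shifts_eutectic(self, walden_system):
        eut_ideal = eutectic_point(walden_system)
        nonideal = BinarySystem(
            props1=walden_system.props1,
            props2=walden_system.props2,
            coeffs1=RKCoefficients((-30_000.0,)),
        )
        eut_ni = eutectic_point(nonideal)
        assert eut_ni.Te < eut_ideal.Te
        assert eut_ni.x1_e > eut_ideal.x1_e
        x_oracle, T_oracle = envelope_minimum_oracle(nonideal)
        assert eut_ni.x1_e == pytest.approx(x_oracle, rel=1e-3)
        assert eut_ni.Te == pytest.approx(T_oracle, abs=1e-4)

    def test_te_bounded_by_low_melting_component(self):
        """With ideal or negatively deviating branches, Te <= Tm2."""
        for a1, a2 in [(0.0, 0.0), (-20_000.0, 0.0), (-20_000.0, -10_000.0)]:
            system = BinarySystem(
                props1=MeltingProperties(500.0, 25_000.0),
                props2=MeltingProperties(400.0, 18_000.0),
                coeffs1=RKCoefficients((a1,) if a1 else ()),
                coeffs2=RKCoefficients((a2,) if a2 else ()),
            )
            assert eutectic_point(system).Te <= 400.0

    def test_label_swap_symmetry_at_equal_melting_points(self):
        system = BinarySystem(
            props1=MeltingProperties(500.0, 30_000.0),
            props2=MeltingProperties(500.0, 12_000.0),
            coeffs1=RKCoefficients((-9_000.0,)),
            coeffs2=RKCoefficients((-2_000.0,)),
        )
        eut = eutectic_point(system)
        eut_sw = eutectic_point(system.swapped())
        assert eut_sw.x1_e == pytest.approx(1.0 - eut.x1_e, abs=1e-9)
        assert eut_sw.Te == pytest.approx(eut.Te, abs=1e-8)

    def test_gamma_at_eutectic_matches_rk_model(self, walden_system):
        system = BinarySystem(
            props1=walden_system.props1,
            props2=walden_system.props2,
            coeffs1=RKCoefficients((-15_000.0,)),
            coeffs2=RKCoefficients((-5_000.0,)),
        )
        eut = eutectic_point(system)
        assert math.log(eut.gamma1_e) == pytest.approx(
            -15_000.0 * (1 - eut.x1_e) ** 2 / (R * eut.Te), rel=1e-12
        )
        assert math.log(eut.gamma2_e) == pytest.approx(
            -5_000.0 * eut.x1_e**2 / (R * eut.Te), rel=1e-12
        )

    def test_disjoint_feasible_ranges_raise_no_eutectic(self):
        """So strongly negative branches that their feasible composition
        windows do not overlap: the liquidus lines never cross."""
        system = BinarySystem(
            props1=MeltingProperties(600.0, 12_000.0),
            props2=MeltingProperties(300.0, 6_000.0),
            coeffs1=RKCoefficients((-50_000.0,)),
            coeffs2=RKCoefficients((-50_000.0,)),
        )
        with pytest.raises(NoEutecticError):
            eutectic_point(system)

    def test_component_order_enforced(self):
        with pytest.raises(ThermoDomainError):
            BinarySystem(
                props1=MeltingProperties(300.0, 16_320.0),
                props2=MeltingProperties(600.0, 32_640.0),
            )

    def test_positive_deviation_warned(self):
        with pytest.warns(PositiveDeviationWarning):
            BinarySystem(
                props1=MeltingProperties(600.0, 32_640.0),
                props2=MeltingProperties(300.0, 16_320.0),
                coeffs1=RKCoefficients((5_000.0,)),
            )


class TestScaleInvariance:
    @pytest.mark.parametrize("lam", [0.1, 1.0, 10.0])
    def test_fixed_entropy_scaling_preserves_shape(self, lam):
        """At fixed melting entropies, scaling both Tm by lambda scales Te by
        lambda and leaves x1_e and the normalized depression unchanged."""
        base = eutectic_point(
            BinarySystem(
                props1=MeltingProperties(600.0, 54.4 * 600.0),
                props2=MeltingProperties(300.0, 54.4 * 300.0),
            )
        )
        scaled = eutectic_point(
            BinarySystem(
                props1=MeltingProperties(600.0 * lam, 54.4 * 600.0 * lam),
                props2=MeltingProperties(300.0 * lam, 54.4 * 300.0 * lam),
            )
        )
        assert scaled.Te == pytest.approx(lam * base.Te, rel=1e-9)
        assert scaled.x1_e == pytest.approx(base.x1_e, rel=1e-9)
        assert scaled.norm_depression == pytest.approx(base.norm_depression, rel=1e-9)

    def test_depression_maximal_when_melting_points_equal(self):
        """At fixed entropy on both sides, the normalized depression
        decreases monotonically with the Tm1/Tm2 ratio."""
        depressions = []
        for ratio in np.arange(1.0, 3.01, 0.25):
            system = BinarySystem(
                props1=MeltingProperties(300.0 * ratio, 54.4 * 300.0 * ratio),
                props2=MeltingProperties(300.0, 54.4 * 300.0),
            )
            depressions.append(eutectic_point(system).norm_depression)
        assert np.all(np.diff(depressions) < 0)
        assert depressions[0] == max(depressions)

    def test_monotone_deepening_in_each_rk_parameter(self, walden_system):
        a_grid = [0.0, -10_000.0, -20_000.0, -30_000.0]
        te_a1 = [
            eutectic_point(
                BinarySystem(
                    props1=walden_system.props1,
                    props2=walden_system.props2,
                    coeffs1=RKCoefficients((a,) if a else ()),
                )
            ).Te
            for a in a_grid
        ]
        te_a2 = [
            eutectic_point(
                BinarySystem(
                    props1=walden_system.props1,
                    props2=walden_system.props2,
                    coeffs2=RKCoefficients((a,) if a else ()),
                )
            ).Te
            for a in a_grid
        ]
        assert np.all(np.diff(te_a1) < 0)
        assert np.all(np.diff(te_a2) <= 0)


class TestNormalizedDepression:
    def test_no_depression_at_reference(self):
        assert normalized_depression(300.0, 300.0) == 0.0

    def test_hand_value(self):
        assert normalized_depression(270.0, 300.0) == pytest.approx(0.1)

    def test_domain_error(self):
        with pytest.raises(ThermoDomainError):
            normalized_depression(270.0, 0.0)


class TestCurvesAndEnvelope:
    def test_branch_endpoints_recover_pure_melting_points(self, walden_system):
        c1 = liquidus_curve(walden_system, 1, [1.0])
        c2 = liquidus_curve(walden_system, 2, [0.0])
        assert c1.T_K.iloc[0] == pytest.approx(600.0)
        assert c2.T_K.iloc[0] == pytest.approx(300.0)

    def test_branch1_curve_decreasing_toward_dilution(self, walden_system):
        grid = np.linspace(0.05, 1.0, 50)
        c1 = liquidus_curve(walden_system, 1, grid)
        assert np.all(np.diff(c1.T_K.to_numpy()) > 0)

    def test_infeasible_points_flagged_not_dropped(self):
        system = BinarySystem(
            props1=MeltingProperties(600.0, 12_000.0),
            props2=MeltingProperties(300.0, 16_320.0),
            coeffs1=RKCoefficients((-30_000.0,)),
        )
        curve = liquidus_curve(system, 1, [0.05, 0.5, 0.95])
        assert list(curve.feasible) == [False, True, True]
        assert len(curve) == 3

    def test_empty_grid_rejected(self, walden_system):
        with pytest.raises(ThermoDomainError):
            liquidus_curve(walden_system, 1, [])

    def test_envelope_minimum_matches_eutectic(self, walden_system):
        eut = eutectic_point(walden_system)
        grid = np.unique(
            np.concatenate([np.geomspace(1e-5, 0.1, 2000), np.linspace(0.1, 0.999, 2000)])
        )
        table = phase_boundary_table(walden_system, grid)
        i = table.T_liquidus_K.idxmin()
        assert table.T_liquidus_K[i] == pytest.approx(eut.Te, abs=1e-3)
        # stable branch switches at the eutectic composition
        assert set(table.stable_branch[table.x1 > 2 * eut.x1_e]) == {1}

    def test_envelope_endpoints(self, walden_system):
        table = phase_boundary_table(walden_system, [1.0])
        assert table.stable_branch.iloc[0] == 1
        assert table.T_liquidus_K.iloc[0] == pytest.approx(600.0)
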