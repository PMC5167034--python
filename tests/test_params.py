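"""Parameter identities, the effective one-species reduction and ODE solutions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from estabkit import (
    CompetitionSetup,
    DeterministicOutcome,
    deterministic_outcome,
    effective_params,
    logistic_mean,
    lv_deterministic,
    species_params_from_delta,
)
from estabkit.params import setup_from_config


class TestDeltaParameterization:
    @pytest.mark.parametrize(
        "delta,lam,mu,N",
        [(0.5, 1.0, 0.0, 10_000), (1.0, 1.5, 0.5, 15_000), (4.0, 4.5, 3.5, 45_000)],
    )
    def test_table_values(self, delta, lam, mu, N):
        sp = species_params_from_delta(delta)
        assert sp.birth_rate == pytest.approx(lam)
        assert sp.death_rate == pytest.approx(mu)
        assert sp.max_pop == pytest.approx(N)

    def test_growth_and_capacity_invariant_in_delta(self):
        """r = 1/day and K = 10,000 exactly for every noise level delta."""
        for delta in np.arange(0.5, 5.01, 0.5):
            sp = species_params_from_delta(delta)
            assert sp.growth_rate == pytest.approx(1.0, abs=1e-12)
            assert sp.carrying_capacity == pytest.approx(10_000.0, rel=1e-12)

    def test_zero_death_rate_forces_K_equal_N(self):
        sp = species_params_from_delta(0.5)
        assert sp.carrying_capacity == sp.max_pop

    def test_delta_below_half_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            species_params_from_delta(0.3)


class TestEffectiveParams:
    def test_no_competition_recovers_intrinsic(self):
        sp = species_params_from_delta(1.0)
        eff = effective_params(sp, 0.0, 10_000)
        assert eff.eff_birth == sp.birth_rate
        assert eff.eff_growth == sp.growth_rate
        assert eff.eff_carrying_capacity == pytest.approx(sp.carrying_capacity)

    def test_symmetric_setup_reduction(self):
        """delta=1, alpha=0.5: effective birth 1.0, growth 0.5, capacity 7,500."""
        sp = species_params_from_delta(1.0)
        eff = effective_params(sp, 0.5, 10_000)
        assert eff.eff_birth == pytest.approx(1.0)
        assert eff.eff_growth == pytest.approx(0.5)
        assert eff.eff_carrying_capacity == pytest.approx(7_500.0)

    def test_pure_death_at_strong_competition(self):
        sp = species_params_from_delta(1.0)
        eff = effective_params(sp, 1.5, 10_000)
        assert eff.eff_birth == 0.0
        assert math.isnan(eff.eff_carrying_capacity)

    def test_clipping_guards_negative_birth(self):
        sp = species_params_from_delta(1.0)
        eff = effective_params(sp, 5.0, 10_000)  # alpha K_R > N
        assert eff.eff_birth == 0.0 and eff.clipped

    @given(
        delta=st.floats(0.5, 5.0),
        a1=st.floats(0.0, 2.0),
        a2=st.floats(0.0, 2.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetric_growth_identity_and_monotonicity(self, delta, a1, a2):
        """With K_R = K_I the effective growth is r(1 - alpha), and the
        effective birth rate is non-increasing in alpha."""
        sp = species_params_from_delta(delta)
        lo, hi = sorted((a1, a2))
        e_lo = effective_params(sp, lo, 10_000)
        e_hi = effective_params(sp, hi, 10_000)
        if not e_lo.clipped:
            assert e_lo.eff_growth == pytest.approx(
                sp.growth_rate * (1.0 - lo), abs=1e-12
            )
        assert e_hi.eff_birth <= e_lo.eff_birth + 1e-12


class TestLogisticMean:
    def test_identity_at_zero_and_asymptote(self):
        assert logistic_mean(0.0, 40, 1.0, 10_000) == pytest.approx(40.0)
        assert logistic_mean(100.0, 40, 1.0, 10_000) == pytest.approx(10_000.0)
        assert logistic_mean(50.0, 40, -0.5, 10_000) == pytest.approx(0.0, abs=1e-6)

    def test_matches_numerical_ode_integration(self):
        sol = solve_ivp(
            lambda t, n: n * (1 - n / 10_000.0),
            (0, 4),
            [40.0],
            rtol=1e-10,
            atol=1e-10,
        )
        assert logistic_mean(4.0, 40, 1.0, 10_000) == pytest.approx(
            sol.y[0, -1], rel=1e-7
        )

    def test_solves_its_ode_residual(self):
        """Finite-difference residual |dn/dt - r n (1 - n/K)| small on a grid."""
        t = np.linspace(0.0, 6.0, 2001)
        n = logistic_mean(t, 40, 1.0, 10_000)
        dn = np.gradient(n, t)
        resid = np.abs(dn - n * (1 - n / 10_000.0))
        assert resid.max() < 1e-4 * 10_000

    def test_overflow_safe_for_large_rt(self):
        assert np.isfinite(logistic_mean(1e4, 40, 10.0, 10_000))


class TestLotkaVolterra:
    def test_decoupled_limit_matches_logistic(self):
        setup = CompetitionSetup.from_delta(1.0, alpha_IR=0.0, alpha_RI=0.0)
        df = lv_deterministic(setup, np.linspace(0, 4, 41))
        oracle = logistic_mean(df["t"].to_numpy(), 40, 1.0, 10_000)
        assert np.allclose(df["n_I"], oracle, rtol=1e-6)

    def test_extinction_is_absorbing(self):
        setup = CompetitionSetup.from_delta(1.0, alpha_IR=0.5, n0_invader=0)
        df = lv_deterministic(setup, np.linspace(0, 4, 11))
        assert np.all(df["n_I"] == 0.0)
        oracle = logistic_mean(df["t"].to_numpy(), 10_000, 1.0, 10_000)
        assert np.allclose(df["n_R"], oracle, rtol=1e-6)

    def test_resident_stays_near_capacity(self):
        """With the default design the resident never drops below 0.99 K_R
        within the 4-day observation window."""
        setup = CompetitionSetup.from_delta(1.0, alpha_IR=0.5)
        df = lv_deterministic(setup, np.linspace(0, 4, 401))
        assert (df["n_R"] / 10_000).min() >= 0.99

    def test_populations_never_negative(self):
        setup = CompetitionSetup.from_delta(2.0, alpha_IR=1.5)
        df = lv_deterministic(setup, np.linspace(0, 20, 201))
        assert (df[["n_I", "n_R"]] >= 0).all().all()

    def test_bad_grid_rejected(self):
        setup = CompetitionSetup.from_delta(1.0, alpha_IR=0.5)
        with pytest.raises(ValueError):
            lv_deterministic(setup, [1.0, 2.0])  # does not start at 0


class TestDeterministicOutcome:
    @pytest.mark.parametrize(
        "alpha,expected",
        [
            (0.5, DeterministicOutcome.ESTABLISH),
            (1.5, DeterministicOutcome.EXTINCT),
            (1.0, DeterministicOutcome.BIFURCATION),
            (0.999999, DeterministicOutcome.ESTABLISH),
        ],
    )
    def test_classification(self, alpha, expected):
        assert deterministic_outcome(alpha) is expected


def test_setup_config_roundtrip():
    setup = CompetitionSetup.from_delta(2.5, alpha_IR=0.8, n0_invader=40)
    again = setup_from_config(setup.to_config())
    assert again == setup
    shorthand = setup_from_config({"delta": 2.5, "alpha_IR": 0.8})
    assert shorthand == setup


def test_setup_config_resident_capacity_override():
    setup = setup_from_config({"delta": 1.0, "alpha_IR": 0.5, "K_R_override": 5_000})
    assert setup.resident.carrying_capacity == pytest.approx(5_000.0)
    # a smaller resident community exerts less pressure on the invader
    assert setup.effective_invader().eff_birth == pytest.approx(
        1.5 * (1 - 0.5 * 5_000 / 15_000)
    )
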