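"""Forward physics: steady states, two-pool exchange, DANTE, Bloch-Siegert."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from boast31p import (
    DantePulseTrain,
    FermiPulse,
    InvalidParameterError,
    PoolSystem,
    SequenceParams,
    bloch_siegert_phase,
    dante_saturation_profile,
    minimum_tr,
    partial_saturation_signal,
    saturated_pool_steady_state,
    steady_state_signal,
    two_pool_propagate,
)
from boast31p.exchange_model import bloch_siegert_k, dante_transient


def spgr_recursion(flip_deg, tr, t1, m0, n=100_000):
    """Independent oracle: iterate rotation-then-recovery to its fixed point."""
    theta = math.radians(flip_deg)
    e1 = math.exp(-tr / t1)
    mz = m0
    for _ in range(n):
        mz_new = m0 + (mz * math.cos(theta) - m0) * e1
        if abs(mz_new - mz) < 1e-15:
            break
        mz = mz_new
    return mz * math.sin(theta)


class TestPartialSaturation:
    def test_fully_relaxed_limit_is_sine(self):
        assert partial_saturation_signal(90.0, 100.0, 1.0, 1.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "flip,expected",
        [(16.0, 0.1765), (64.0, 0.0983)],
    )
    def test_matches_pulse_train_recursion(self, flip, expected):
        direct = partial_saturation_signal(flip, 0.4, 6.0, 1.0)
        assert direct == pytest.approx(spgr_recursion(flip, 0.4, 6.0, 1.0), rel=1e-10)
        assert direct == pytest.approx(expected, abs=5e-5)

    def test_rejects_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            partial_saturation_signal(16.0, 0.4, -1.0, 1.0)
        with pytest.raises(InvalidParameterError):
            partial_saturation_signal(16.0, -0.4, 6.0, 1.0)


class TestSaturatedSteadyState:
    def test_no_exchange_leaves_pool_untouched(self):
        t1p, m0p = saturated_pool_steady_state(PoolSystem(m0_pcr=1.0, kf=0.0))
        assert (t1p, m0p) == (6.0, 1.0)

    def test_matches_ode_propagation(self):
        """Oracle: propagate dMz/dt = (M0-Mz)/T1 - kf*Mz to equilibrium."""
        pools = PoolSystem(m0_pcr=1.0, m0_atp=1.0 / 1.5)
        sol = solve_ivp(
            lambda t, m: (1.0 - m) / 6.0 - 0.32 * m,
            (0.0, 300.0),
            [1.0],
            rtol=1e-12,
            atol=1e-14,
        )
        t1p, m0p = saturated_pool_steady_state(pools)
        assert m0p == pytest.approx(sol.y[0, -1], rel=1e-8)
        assert t1p == pytest.approx(2.0548, abs=1e-4)
        assert m0p == pytest.approx(0.34247, abs=1e-5)

    def test_rate_equation_round_trip_recovers_kf(self):
        pools = PoolSystem(m0_pcr=1.0, m0_atp=1.0 / 1.5)
        t1p, m0p = saturated_pool_steady_state(pools)
        kf = (1.0 / t1p) * (1.0 - m0p / 1.0)
        assert kf == pytest.approx(0.32, rel=1e-12)


class TestTwoPoolPropagate:
    def test_decoupled_pools_match_single_pool_form(self):
        pools = PoolSystem(m0_pcr=1.0, m0_atp=1.0 / 1.5, kf=0.0)
        seq = SequenceParams(tr=0.4, flip=30.0)
        pcr, gatp = steady_state_signal(pools, seq)
        assert pcr == pytest.approx(partial_saturation_signal(30.0, 0.4, 6.0, 1.0), rel=1e-12)
        assert gatp == pytest.approx(
            partial_saturation_signal(30.0, 0.4, 2.0, 1.0 / 1.5), rel=1e-12
        )

    @pytest.mark.parametrize("flip,expected", [(16.0, 0.0800), (64.0, 0.0852)])
    def test_saturated_signal_matches_closed_form(self, flip, expected):
        """Under full saturation the PCr channel is exactly the (T1', M0') pulse train."""
        pools = PoolSystem(m0_pcr=1.0, m0_atp=1.0 / 1.5)
        seq = SequenceParams(tr=0.4, flip=flip, saturation="gamma_atp", sat_fraction=1.0)
        pcr, gatp = steady_state_signal(pools, seq)
        t1p, m0p = saturated_pool_steady_state(pools)
        assert pcr == pytest.approx(partial_saturation_signal(flip, 0.4, t1p, m0p), rel=1e-9)
        assert pcr == pytest.approx(expected, abs=5e-5)
        assert gatp == 0.0

    def test_fixed_point_matches_iteration_for_random_parameters(self, rng):
        """Steady state equals long iterative propagation to 1e-9 relative."""
        for _ in range(1000):
            pools = PoolSystem(
                m0_pcr=rng.uniform(0.5, 3.0),
                m0_atp=rng.uniform(0.5, 3.0),
                t1_pcr=rng.uniform(1.0, 10.0),
                t1_gatp=rng.uniform(0.3, 5.0),
                kf=rng.uniform(0.0, 1.0),
            )
            seq = SequenceParams(
                tr=rng.uniform(0.2, 2.0),
                flip=rng.uniform(5.0, 170.0),
                saturation=rng.choice(["gamma_atp", "none"]),
                sat_fraction=rng.uniform(0.0, 1.0),
            )
            fixed = two_pool_propagate(pools, seq)
            iterated = two_pool_propagate(pools, seq, n_reps=100_000, tol=1e-14)
            assert fixed[0] == pytest.approx(iterated[0], rel=1e-9, abs=1e-12)
            assert fixed[1] == pytest.approx(iterated[1], rel=1e-9, abs=1e-12)

    def test_faster_exchange_shortens_apparent_t1_and_m0(self):
        vals = [saturated_pool_steady_state(PoolSystem(kf=kf)) for kf in (0.1, 0.32, 0.6)]
        t1s = [v[0] for v in vals]
        m0s = [v[1] for v in vals]
        assert t1s == sorted(t1s, reverse=True)
        assert m0s == sorted(m0s, reverse=True)

    def test_steady_state_magnetization_bounded_by_equilibrium(self, rng):
        for _ in range(50):
            pools = PoolSystem(kf=0.0)
            seq = SequenceParams(tr=rng.uniform(0.2, 3.0), flip=rng.uniform(1.0, 179.0))
            mz = two_pool_propagate(pools, seq)
            assert mz[0] <= pools.m0_pcr + 1e-12
            assert mz[1] <= pools.m0_atp + 1e-12


class TestMinimumTr:
    @pytest.mark.parametrize(
        "dead,frac,expected",
        [(0.090, 0.76, 0.375), (0.090, 0.0, 0.090), (0.120, 0.5, 0.240)],
    )
    def test_closed_form(self, dead, frac, expected):
        assert minimum_tr(dead, frac) == pytest.approx(expected, rel=1e-12)

    def test_rejects_full_saturation_fraction(self):
        with pytest.raises(InvalidParameterError):
            minimum_tr(0.09, 1.0)


class TestDante:
    def test_no_rf_leaves_magnetization_at_equilibrium(self):
        prof = dante_saturation_profile(DantePulseTrain(), [0.0])
        assert prof.residual_mz[0] == pytest.approx(1.0)
        assert prof.q[0] == pytest.approx(1.0)

    def test_on_resonance_saturation_across_b1_range(self):
        """The train destroys the on-resonance peak for 50-800 Hz amplitudes."""
        prof = dante_saturation_profile(DantePulseTrain(), np.linspace(50, 800, 16))
        assert prof.residual_mz.max() < 0.1

    def test_far_offset_spares_magnetization(self):
        near = dante_saturation_profile(DantePulseTrain(), [400.0], offset=289.0)
        far = dante_saturation_profile(DantePulseTrain(), [400.0], offset=1e6)
        assert far.q[0] > 0.999
        assert far.q[0] > near.q[0]

    def test_transient_approaches_periodic_steady_state(self):
        train = DantePulseTrain(gamma_b1=200.0)
        mz = dante_transient(train, 289.0, 6.0, 0.1, duration=60.0)
        prof = dante_saturation_profile(DantePulseTrain(), [200.0])
        assert mz == pytest.approx(prof.q[0], abs=2e-3)

    def test_coarse_time_step_is_refused(self):
        with pytest.raises(InvalidParameterError):
            dante_transient(DantePulseTrain(gamma_b1=100.0), 0.0, 2.0, 0.03, 1.0, dt=5e-4)


class TestBlochSiegert:
    def test_zero_amplitude_gives_zero_phase(self):
        assert bloch_siegert_phase(FermiPulse(peak_gamma_b1=0.0)) == 0.0

    def test_phase_is_antisymmetric_in_offset(self):
        pos = bloch_siegert_phase(FermiPulse(offset=2000.0))
        neg = bloch_siegert_phase(FermiPulse(offset=-2000.0))
        assert pos == pytest.approx(-neg, rel=1e-12)
        assert pos > 0

    def test_matches_quadrature_and_adiabatic_oracle(self):
        """Riemann-sum quadrature and the exact adiabatic phase agree.

        The exact phase of adiabatic following is the integral of
        sqrt(delta^2 + w1(t)^2) - delta; the quadratic approximation differs
        by O((w1/delta)^2), below 2% at the validity bound enforced here.
        """
        pulse = FermiPulse(tp=3.5, t0=0.875, a=0.224, offset=2000.0, peak_gamma_b1=500.0)
        t = np.linspace(-pulse.tp / 2, pulse.tp / 2, 200_001) * 1e-3
        g = pulse.peak_gamma_b1 / (1.0 + np.exp((np.abs(t * 1e3) - pulse.t0) / pulse.a))
        riemann = np.trapezoid(math.pi * g**2 / pulse.offset, t)
        phase = bloch_siegert_phase(pulse)
        assert phase == pytest.approx(riemann, rel=1e-6)
        delta = 2 * math.pi * pulse.offset
        exact = np.trapezoid(np.sqrt(delta**2 + (2 * math.pi * g) ** 2) - delta, t)
        assert phase == pytest.approx(exact, rel=0.02)

    def test_k_factor_scales_quadratically(self):
        pulse = FermiPulse(peak_gamma_b1=300.0, offset=4000.0)
        assert bloch_siegert_phase(pulse) == pytest.approx(
            bloch_siegert_k(pulse) * 300.0**2, rel=1e-9
        )

    def test_on_resonance_pulse_is_rejected(self):
        with pytest.raises(InvalidParameterError):
            bloch_siegert_phase(FermiPulse(offset=0.0))
        with pytest.raises(InvalidParameterError):
            bloch_siegert_phase(FermiPulse(offset=500.0, peak_gamma_b1=500.0))
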