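"""Two-pool chemical-exchange physics for saturation-transfer 31P-MRS.

The creatine-kinase reaction places phosphocreatine (PCr) and the terminal
phosphate of ATP (gamma-ATP) in two-way chemical exchange.  This module
provides the forward models needed by a four-angle saturation-transfer
experiment:

* the single-pool partially-saturated steady state of a spoiled pulse train,
* the longitudinal Bloch-McConnell dynamics of the exchanging pair under
  pulsed excitation, with or without selective gamma-ATP saturation,
* the frequency-selective saturation profile of a DANTE pulse train,
* the Bloch-Siegert phase of an off-resonance Fermi pulse (the basis of
  phase-based B1+ mapping),
* the minimum repetition time compatible with a required saturation duty
  cycle.

Angles are degrees at every public interface and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm

__all__ = [
    "PoolSystem",
    "SequenceParams",
    "DantePulseTrain",
    "FermiPulse",
    "partial_saturation_signal",
    "saturated_pool_steady_state",
    "two_pool_propagate",
    "steady_state_signal",
    "minimum_tr",
    "dante_saturation_profile",
    "dante_transient",
    "bloch_siegert_phase",
    "bloch_siegert_k",
    "InvalidParameterError",
]

#: Assumed 31P Larmor frequency (MHz) fixed by the 2.4 ppm <-> 289 Hz
#: PCr to gamma-ATP separation at 7 T.
REFERENCE_FREQ_MHZ = 289.0 / 2.4

PCR_GATP_SHIFT_PPM = 2.4
PCR_GATP_SHIFT_HZ = 289.0


class InvalidParameterError(ValueError):
    """A physical parameter violates its validity constraints."""


@dataclass(frozen=True)
class PoolSystem:
    """The two exchanging magnetization pools (PCr and gamma-ATP).

    Parameters
    ----------
    m0_pcr, m0_atp:
        Equilibrium longitudinal amplitudes in arbitrary (but common) units.
        Their ratio is the tissue [PCr]:[ATP]; the myocardial default is
        1.5:1.
    t1_pcr, t1_gatp:
        Intrinsic longitudinal relaxation times T1* (s) of each pool, i.e.
        the values that would be observed with exchange switched off.
    kf:
        Pseudo first-order forward rate constant PCr -> gamma-ATP (1/s).
        The reverse rate is derived from detailed balance
        ``kr * m0_atp == kf * m0_pcr`` and is never an independent input.
    """

    m0_pcr: float = 1.5
    m0_atp: float = 1.0
    t1_pcr: float = 6.0
    t1_gatp: float = 2.0
    kf: float = 0.32
    shift_ppm: float = PCR_GATP_SHIFT_PPM

    def __post_init__(self) -> None:
        for name in ("m0_pcr", "m0_atp", "t1_pcr", "t1_gatp"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.kf < 0:
            raise InvalidParameterError("kf must be non-negative")

    @property
    def kr(self) -> float:
        """Reverse rate constant (1/s) from detailed balance."""
        return self.kf * self.m0_pcr / self.m0_atp

    @property
    def shift_hz(self) -> float:
        """Chemical-shift separation in Hz at the reference frequency."""
        return self.shift_ppm * REFERENCE_FREQ_MHZ

    @property
    def pcr_atp_ratio(self) -> float:
        return self.m0_pcr / self.m0_atp

    def with_(self, **kwargs) -> "PoolSystem":
        """Return a copy with the given fields replaced."""
        values = {
            "m0_pcr": self.m0_pcr,
            "m0_atp": self.m0_atp,
            "t1_pcr": self.t1_pcr,
            "t1_gatp": self.t1_gatp,
            "kf": self.kf,
            "shift_ppm": self.shift_ppm,
        }
        values.update(kwargs)
        return PoolSystem(**values)


SATURATION_MODES = ("gamma_atp", "control", "none")


@dataclass(frozen=True)
class SequenceParams:
    """One acquisition step of a pulsed saturation-transfer sequence.

    ``sat_fraction`` is the fraction of each TR during which the selective
    saturation train runs; the remaining ``(1 - sat_fraction) * tr`` is the
    dead time (excitation, readout, spoiling).  ``saturation`` selects
    on-resonance gamma-ATP saturation, mirrored control irradiation (which
    leaves both pools untouched apart from a spillover factor applied at the
    amplitude level), or no irradiation at all.
    """

    tr: float
    flip: float
    saturation: str = "none"
    sat_fraction: float = 0.0
    n_points: int = 512
    bandwidth: float = 6000.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise InvalidParameterError("tr must be positive")
        if not (0 < self.flip < 180):
            raise InvalidParameterError("flip must lie in (0, 180) degrees")
        if not (0.0 <= self.sat_fraction <= 1.0):
            raise InvalidParameterError("sat_fraction must lie in [0, 1]")
        if self.saturation not in SATURATION_MODES:
            raise InvalidParameterError(
                f"saturation must be one of {SATURATION_MODES}"
            )

    @property
    def dead_time(self) -> float:
        """Unsaturated time per TR (s)."""
        return self.tr * (1.0 - self.sat_fraction)


@dataclass(frozen=True)
class DantePulseTrain:
    """A fixed-amplitude DANTE train: short hard pulses separated by gaps.

    ``t_on``/``t_off`` are the pulse and gap durations in microseconds;
    ``gamma_b1`` is the on-pulse saturation field amplitude in Hz.  The
    default timing (100 us on, 230 us off) saturates the carrier over a wide
    range of B1+ while sparing resonances a few hundred Hz away.
    """

    t_on: float = 100.0
    t_off: float = 230.0
    gamma_b1: float = 0.0
    modulation_m: int = 1

    def __post_init__(self) -> None:
        if self.t_on <= 0 or self.t_off <= 0:
            raise InvalidParameterError("t_on and t_off must be positive")
        if self.gamma_b1 < 0:
            raise InvalidParameterError("gamma_b1 must be non-negative")

    @property
    def period_s(self) -> float:
        return (self.t_on + self.t_off) * 1e-6


@dataclass(frozen=True)
class FermiPulse:
    """Fermi-envelope off-resonance pulse used for Bloch-Siegert B1 mapping.

    Envelope ``gB1(t) = peak / (1 + exp((|t| - t0) / a))`` truncated to a
    total width ``tp``; all times in ms, amplitudes in Hz.  ``offset`` is the
    carrier offset from PCr in Hz (the default +/-2000 Hz keeps the pulse far
    off-resonance for every metabolite).
    """

    tp: float = 3.5
    t0: float = 0.875
    a: float = 0.224
    offset: float = 2000.0
    peak_gamma_b1: float = 500.0

    def __post_init__(self) -> None:
        if self.tp <= 0 or self.t0 <= 0 or self.a <= 0:
            raise InvalidParameterError("tp, t0 and a must be positive")

    def envelope(self, t_ms: np.ndarray) -> np.ndarray:
        """gamma-B1 (Hz) at times ``t_ms`` (ms, centred on the pulse)."""
        t = np.asarray(t_ms, dtype=float)
        out = self.peak_gamma_b1 / (1.0 + np.exp((np.abs(t) - self.t0) / self.a))
        return np.where(np.abs(t) <= self.tp / 2.0, out, 0.0)


# ---------------------------------------------------------------------------
# Single-pool steady state
# ---------------------------------------------------------------------------

def partial_saturation_signal(flip: float, tr: float, t1: float, m0: float = 1.0):
    """Steady-state signal of an ideally spoiled pulse train.

    ``M(theta) = sin(theta) * m0 * (1 - E) / (1 - cos(theta) * E)`` with
    ``E = exp(-tr / t1)``.  Accepts array inputs (broadcast).  As
    ``tr/t1 -> inf`` the result tends to ``m0 * sin(flip)``.
    """
    flip = np.asarray(flip, dtype=float)
    tr = np.asarray(tr, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0) or np.any(tr <= 0):
        raise InvalidParameterError("t1 and tr must be positive")
    if np.any((flip <= 0) | (flip >= 180)):
        raise InvalidParameterError("flip must lie in (0, 180) degrees")
    theta = np.deg2rad(flip)
    e1 = np.exp(-tr / t1)
    out = np.sin(theta) * m0 * (1.0 - e1) / (1.0 - np.cos(theta) * e1)
    return out if out.ndim else float(out)


def saturated_pool_steady_state(pools: PoolSystem) -> tuple[float, float]:
    """Apparent (T1', M0') of PCr under ideal continuous gamma-ATP saturation.

    With the partner pool clamped to zero, PCr relaxes mono-exponentially
    with rate ``1/T1' = 1/T1*_PCr + kf`` toward
    ``M0' = m0_pcr * (1/T1*_PCr) / (1/T1')``.  Feeding (T1', M0', M0) back
    through the saturation-transfer rate equation recovers kf exactly.
    """
    r1_app = 1.0 / pools.t1_pcr + pools.kf
    t1_prime = 1.0 / r1_app
    m0_prime = pools.m0_pcr * (1.0 / pools.t1_pcr) / r1_app
    return t1_prime, m0_prime


# ---------------------------------------------------------------------------
# Two-pool Bloch-McConnell propagation
# ---------------------------------------------------------------------------

def _generator(pools: PoolSystem) -> tuple[np.ndarray, np.ndarray]:
    """2x2 longitudinal exchange-relaxation generator A and inflow b.

    dMz/dt = A @ Mz + b for Mz = (Mz_PCr, Mz_gATP).
    """
    a = np.array(
        [
            [-1.0 / pools.t1_pcr - pools.kf, pools.kr],
            [pools.kf, -1.0 / pools.t1_gatp - pools.kr],
        ]
    )
    b = np.array([pools.m0_pcr / pools.t1_pcr, pools.m0_atp / pools.t1_gatp])
    return a, b


def _affine_segment(a: np.ndarray, b: np.ndarray, t: float):
    """Propagator (E, f) with M(t) = E @ M0 + f for dM/dt = A M + b."""
    e = expm(a * t)
    m_ss = np.linalg.solve(a, -b)
    f = (np.eye(len(b)) - e) @ m_ss
    return e, f


def _tr_map(pools: PoolSystem, seq: SequenceParams):
    """Affine map (E, f) over one full TR, sampled just before the pulse.

    Segment order within a TR: instantaneous excitation (Mz scaled by
    cos(flip) in both pools, ideal spoiling assumed), dead time with free
    two-pool evolution, then the saturated segment (gamma-ATP clamped to
    zero) when saturation is on-resonance.
    """
    cos_flip = math.cos(math.radians(seq.flip))
    sat_time = seq.tr * seq.sat_fraction if seq.saturation == "gamma_atp" else 0.0
    free_time = seq.tr - sat_time

    a_free, b_free = _generator(pools)
    e = np.eye(2) * cos_flip
    f = np.zeros(2)
    if free_time > 0:
        e_seg, f_seg = _affine_segment(a_free, b_free, free_time)
        e, f = e_seg @ e, e_seg @ f + f_seg
    if sat_time > 0:
        # gamma-ATP clamped: PCr evolves alone, ATP row forced to zero.
        lam = 1.0 / pools.t1_pcr + pools.kf
        decay = math.exp(-lam * sat_time)
        m_inf = (pools.m0_pcr / pools.t1_pcr) / lam
        e_seg = np.array([[decay, 0.0], [0.0, 0.0]])
        f_seg = np.array([(1.0 - decay) * m_inf, 0.0])
        e, f = e_seg @ e, e_seg @ f + f_seg
    return e, f


def two_pool_propagate(
    pools: PoolSystem,
    seq: SequenceParams,
    n_reps: int | None = None,
    tol: float = 1e-12,
) -> tuple[float, float]:
    """Longitudinal magnetizations just before the excitation pulse.

    Propagates the two-pool Bloch-McConnell system through the pulsed
    sequence by exact piecewise-constant integration (matrix exponential of
    the 2x2 generator per segment, instantaneous rotations, gamma-ATP
    clamped during saturated segments).

    Parameters
    ----------
    n_reps:
        Number of TRs to propagate from thermal equilibrium; the returned
        state is the one just before pulse ``n_reps``.  ``None`` (default)
        returns the steady state, obtained directly as the fixed point of
        the per-TR affine map.
    """
    e, f = _tr_map(pools, seq)
    if n_reps is None:
        spectral_radius = max(abs(np.linalg.eigvals(e)))
        if spectral_radius >= 1.0:  # impossible for valid relaxing systems
            raise RuntimeError("per-TR propagation is not contractive")
        m = np.linalg.solve(np.eye(2) - e, f)
    else:
        if n_reps < 1:
            raise InvalidParameterError("n_reps must be >= 1")
        m = np.array([pools.m0_pcr, pools.m0_atp])
        for _ in range(n_reps - 1):
            m_next = e @ m + f
            if np.max(np.abs(m_next - m)) < tol * max(1.0, np.max(np.abs(m))):
                m = m_next
                break
            m = m_next
    return float(m[0]), float(m[1])


def steady_state_signal(pools: PoolSystem, seq: SequenceParams) -> tuple[float, float]:
    """Observed steady-state amplitudes ``Mz * sin(flip)`` of both pools."""
    mz_pcr, mz_gatp = two_pool_propagate(pools, seq)
    s = math.sin(math.radians(seq.flip))
    return mz_pcr * s, mz_gatp * s


# ---------------------------------------------------------------------------
# Timing
# ---------------------------------------------------------------------------

def minimum_tr(dead_time: float, required_sat_fraction: float) -> float:
    """Shortest TR whose saturated fraction meets the requirement.

    With ``dead_time`` seconds of each TR necessarily unsaturated (readout,
    excitation, spoiling), a saturation duty cycle of at least
    ``required_sat_fraction`` demands ``TR >= dead_time / (1 - fraction)``.
    """
    if dead_time <= 0:
        raise InvalidParameterError("dead_time must be positive")
    if not (0.0 <= required_sat_fraction < 1.0):
        raise InvalidParameterError("required_sat_fraction must lie in [0, 1)")
    return dead_time / (1.0 - required_sat_fraction)


# ---------------------------------------------------------------------------
# DANTE saturation profile
# ---------------------------------------------------------------------------

def _bloch_matrix(omega1: float, delta: float, t1: float, t2: float):
    """Full 3-component Bloch generator (rotating frame, RF along x)."""
    a = np.array(
        [
            [-1.0 / t2, delta, 0.0],
            [-delta, -1.0 / t2, omega1],
            [0.0, -omega1, -1.0 / t1],
        ]
    )
    b = np.array([0.0, 0.0, 1.0 / t1])  # M0 = 1
    return a, b


def _dante_steady_mz(
    gamma_b1: float, offset_hz: float, train: DantePulseTrain, t1: float, t2: float
) -> float:
    """Periodic steady-state Mz/M0 of a spin at ``offset_hz`` from the carrier."""
    if gamma_b1 == 0.0:
        return 1.0
    delta = 2.0 * math.pi * offset_hz
    omega1 = 2.0 * math.pi * gamma_b1
    a_on, b_on = _bloch_matrix(omega1, delta, t1, t2)
    a_off, b_off = _bloch_matrix(0.0, delta, t1, t2)
    e_on, f_on = _affine_segment(a_on, b_on, train.t_on * 1e-6)
    e_off, f_off = _affine_segment(a_off, b_off, train.t_off * 1e-6)
    # One period: pulse then gap; steady state sampled at the end of the gap.
    e = e_off @ e_on
    f = e_off @ f_on + f_off
    m = np.linalg.solve(np.eye(3) - e, f)
    return float(m[2])


def dante_transient(
    train: DantePulseTrain,
    offset_hz: float,
    t1: float,
    t2: float,
    duration: float,
    dt: float | None = None,
) -> float:
    """Mz/M0 after integrating the train for ``duration`` seconds from equilibrium.

    ``dt`` is accepted for compatibility with step-based integrators and is
    validated against the pulse width: a step coarser than ``t_on`` cannot
    resolve the train and is refused.  The integration itself is exact
    (piecewise matrix exponentials), so ``dt`` otherwise has no effect.
    """
    if dt is not None and dt > train.t_on * 1e-6:
        raise InvalidParameterError(
            "integration step coarser than the pulse width undersamples the train"
        )
    period = train.period_s
    if duration < 10 * period:
        raise InvalidParameterError("duration must cover many pulse periods")
    delta = 2.0 * math.pi * offset_hz
    omega1 = 2.0 * math.pi * train.gamma_b1
    a_on, b_on = _bloch_matrix(omega1, delta, t1, t2)
    a_off, b_off = _bloch_matrix(0.0, delta, t1, t2)
    e_on, f_on = _affine_segment(a_on, b_on, train.t_on * 1e-6)
    e_off, f_off = _affine_segment(a_off, b_off, train.t_off * 1e-6)
    e = e_off @ e_on
    f = e_off @ f_on + f_off
    n_periods = int(duration // period)
    m = np.array([0.0, 0.0, 1.0])
    # log-time squaring of the period map keeps long durations cheap
    e_pow, f_pow = np.eye(3), np.zeros(3)
    n = n_periods
    while n:
        if n & 1:
            e_pow, f_pow = e @ e_pow, e @ f_pow + f
        e, f = e @ e, e @ f + f
        n >>= 1
    m = e_pow @ m + f_pow
    return float(m[2])


def dante_saturation_profile(
    train: DantePulseTrain,
    gamma_b1_range,
    offset: float = PCR_GATP_SHIFT_HZ,
    t1_on: float = 2.0,
    t2_on: float = 0.03,
    t1_off: float = 6.0,
    t2_off: float = 0.1,
) -> "np.recarray":
    """Saturation and sparing of a DANTE train across B1+ amplitudes.

    For each ``gamma_b1`` (Hz) in ``gamma_b1_range`` the full three-component
    Bloch equations are integrated to the periodic steady state, twice: once
    on resonance (the saturated peak, relaxation ``t1_on``/``t2_on``;
    defaults are gamma-ATP-like) and once at ``offset`` Hz (the spared peak,
    ``t1_off``/``t2_off``; defaults are PCr-like).

    Returns a record array with fields ``gamma_b1_hz``, ``residual_mz``
    (on-resonance Mz/M0, << 1 for good saturation) and ``q`` (preserved
    fraction at the offset, ideally ~1).
    """
    if t2_on <= 0 or t2_off <= 0:
        raise InvalidParameterError("T2 values must be positive")
    gb1 = np.atleast_1d(np.asarray(gamma_b1_range, dtype=float))
    out = np.recarray(gb1.shape, dtype=[("gamma_b1_hz", float), ("residual_mz", float), ("q", float)])
    for i, g in enumerate(gb1):
        tr = DantePulseTrain(train.t_on, train.t_off, float(g), train.modulation_m)
        out.gamma_b1_hz[i] = g
        out.residual_mz[i] = _dante_steady_mz(float(g), 0.0, tr, t1_on, t2_on)
        out.q[i] = _dante_steady_mz(float(g), offset, tr, t1_off, t2_off)
    return out


# ---------------------------------------------------------------------------
# Bloch-Siegert phase
# ---------------------------------------------------------------------------

def bloch_siegert_phase(pulse: FermiPulse) -> float:
    """Phase (rad) accrued by on-resonance spins during the off-resonance pulse.

    In the regime ``|offset| >> gamma_b1`` the Bloch-Siegert phase is

        phi = integral (2 pi gB1(t))^2 / (2 * 2 pi * offset) dt
            = integral pi * gB1(t)^2 / offset dt,

    antisymmetric in the sign of the offset and quadratic in the pulse
    amplitude.  Evaluated by adaptive quadrature of the Fermi envelope.
    """
    if pulse.offset == 0:
        raise InvalidParameterError("offset must be non-zero (off-resonance pulse)")
    if pulse.peak_gamma_b1 == 0:
        return 0.0
    if abs(pulse.offset) < 4.0 * pulse.peak_gamma_b1:
        raise InvalidParameterError(
            "Bloch-Siegert approximation requires |offset| >= 4 * peak_gamma_b1"
        )

    def integrand(t_ms: float) -> float:
        g = pulse.peak_gamma_b1 / (1.0 + math.exp((abs(t_ms) - pulse.t0) / pulse.a))
        return math.pi * g * g / pulse.offset * 1e-3  # ms -> s

    half = pulse.tp / 2.0
    val, _ = quad(integrand, 0.0, half, limit=200)
    return 2.0 * val


def bloch_siegert_k(pulse: FermiPulse) -> float:
    """K_BS (rad / Hz^2): phase per unit squared peak amplitude."""
    unit = FermiPulse(pulse.tp, pulse.t0, pulse.a, pulse.offset, 1.0)
    # |offset| >> 1 Hz always holds for the unit-amplitude pulse
    return bloch_siegert_phase(unit)
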