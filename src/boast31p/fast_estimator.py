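"""Four-angle saturation-transfer (FAST/BOAST) inverse problem.

Given steady-state PCr amplitudes acquired at two flip angles, each with and
without selective gamma-ATP saturation, this module recovers the apparent
relaxation times T1' and T1, the equilibrium amplitudes M0' and M0, the
creatine-kinase forward rate constant

    kf = (1/T1') * (1 - M0'/M0),

the direct-saturation spillover factor Q, and, with a literature ATP
concentration, [PCr] and the CK flux.  It also provides the multiparametric
Bloch-McConnell least-squares fit, variance- and n-weighted literature
means, B1-error propagation, and conversion of Bloch-Siegert phase maps to
B1/flip-angle maps.

Noise-driven non-physical intermediates (e.g. a dual-angle log argument
outside (0, 1)) are returned as NaN and surfaced with reason codes; they are
never raised as exceptions or silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exchange_model import (
    FermiPulse,
    InvalidParameterError,
    PoolSystem,
    SequenceParams,
    bloch_siegert_k,
    partial_saturation_signal,
    saturated_pool_steady_state,
    steady_state_signal,
)

__all__ = [
    "SaturationTransferSet",
    "KineticResult",
    "FluxResult",
    "estimate_t1_dual_angle",
    "estimate_m0_dual_angle",
    "estimate_kf",
    "compute_q",
    "estimate_all",
    "concentration_and_flux",
    "variance_weighted_mean",
    "n_weighted_mean",
    "fit_bloch_mcconnell",
    "propagate_b1_error",
    "b1_map_from_phase_pair",
    "flip_map_from_b1",
]

#: Variance-weighted literature mean of myocardial [ATP] (mmol/kg wet weight).
DEFAULT_ATP_CONC = 5.82
DEFAULT_ATP_CONC_SD = 0.40


# ---------------------------------------------------------------------------
# Dual-angle algebra (vectorized; NaN marks noise-driven non-physical results)
# ---------------------------------------------------------------------------

def estimate_t1_dual_angle(m_a, m_b, alpha: float, beta: float, tr: float):
    """Apparent T1 (s) from a dual-angle steady-state amplitude pair.

    ``T1 = -TR / ln[(sin a - R sin b) / (cos b sin a - R cos a sin b)]`` with
    ``R = m_a / m_b``.  This is the exact inverse of the spoiled steady-state
    signal equation evaluated at the two flips.  Arguments outside (0, 1)
    (possible under noise, or for fully relaxed amplitudes where TR/T1 -> 0)
    yield NaN rather than an exception.
    """
    a, b = math.radians(alpha), math.radians(beta)
    if math.isclose(a, b):
        raise InvalidParameterError("alpha and beta must differ")
    m_a = np.asarray(m_a, dtype=float)
    m_b = np.asarray(m_b, dtype=float)
    r = m_a / m_b
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (math.sin(a) - r * math.sin(b)) / (
            math.cos(b) * math.sin(a) - r * math.cos(a) * math.sin(b)
        )
        arg = np.where((arg > 0.0) & (arg < 1.0), arg, np.nan)
        out = -tr / np.log(arg)
    return out if out.ndim else float(out)


def _m0_form_a(m_a, r, a: float, b: float):
    num = m_a * (math.cos(b) - math.cos(a))
    den = math.sin(a) * (math.cos(b) - 1.0) - r * math.sin(b) * (math.cos(a) - 1.0)
    return num / den


def _m0_form_b(m_b, r, a: float, b: float):
    num = m_b * (math.cos(a) - math.cos(b))
    den = math.sin(b) * (math.cos(a) - 1.0) - math.sin(a) * (math.cos(b) - 1.0) / r
    return num / den


def estimate_m0_dual_angle(m_a, m_b, alpha: float, beta: float, check_tol: float | None = 1e-10):
    """Equilibrium amplitude M0 from a dual-angle steady-state pair.

    Two algebraically equivalent closed forms exist (one anchored on the
    alpha amplitude, one on the beta amplitude); both are evaluated and
    asserted to agree to ``check_tol`` relative wherever finite.  Degenerate
    denominators yield NaN.  The result is linear in the amplitudes and does
    not require TR.
    """
    a, b = math.radians(alpha), math.radians(beta)
    m_a = np.asarray(m_a, dtype=float)
    m_b = np.asarray(m_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = m_a / m_b
        out_a = _m0_form_a(m_a, r, a, b)
        out_b = _m0_form_b(m_b, r, a, b)
    if check_tol is not None:
        both = np.isfinite(out_a) & np.isfinite(out_b) & (np.abs(out_a) > 0)
        if np.any(both):
            rel = np.abs(out_a - out_b)[both] / np.abs(out_a)[both]
            if np.max(rel) > check_tol:
                raise AssertionError(
                    f"dual-form M0 mismatch: max relative difference {np.max(rel):.3e}"
                )
    out = np.where(np.isfinite(out_a), out_a, np.nan)
    return out if out.ndim else float(out)


def estimate_kf(t1_prime, m0_prime, m0):
    """Forward rate constant ``kf = (1/T1') * (1 - M0'/M0)`` in 1/s.

    Negative values (possible under noise when M0' > M0) are returned as-is
    so that cohort averaging remains unbiased; callers that need a physical
    value should clip at zero and report the clipping.
    """
    t1_prime = np.asarray(t1_prime, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if np.any(m0 == 0):
        raise InvalidParameterError("m0 must be non-zero")
    out = (1.0 / t1_prime) * (1.0 - np.asarray(m0_prime, dtype=float) / m0)
    return out if out.ndim else float(out)


def compute_q(m0_ctrl, m0_unsat):
    """Spillover factor Q: control-saturation PCr over unsaturated PCr (ideal 1)."""
    out = np.asarray(m0_ctrl, dtype=float) / np.asarray(m0_unsat, dtype=float)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Per-voxel containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaturationTransferSet:
    """The 4-5 per-voxel PCr amplitudes a four-angle experiment yields.

    ``m_*_sat`` are acquired under gamma-ATP saturation, ``m_*_ctrl`` under
    mirrored control saturation, at flip angles ``alpha`` and ``beta``
    (degrees).  ``m_unsat`` is the optional no-saturation scan (acquired at
    the beta flip by default) used to measure Q.  ``m_gatp_unsat`` and
    ``m_aatp_unsat`` are the unsaturated gamma- and alpha-ATP amplitudes
    needed by the multiparametric fit.  Each amplitude carries its own SD
    (typically the CRLB from spectral fitting).
    """

    m_alpha_sat: float
    m_beta_sat: float
    m_alpha_ctrl: float
    m_beta_ctrl: float
    sd_alpha_sat: float = 0.0
    sd_beta_sat: float = 0.0
    sd_alpha_ctrl: float = 0.0
    sd_beta_ctrl: float = 0.0
    m_unsat: float | None = None
    sd_unsat: float = 0.0
    m_gatp_unsat: float | None = None
    sd_gatp_unsat: float = 0.0
    m_aatp_unsat: float | None = None
    sd_aatp_unsat: float = 0.0
    # ATP amplitudes from the control scans (gamma- and alpha-ATP are not
    # saturated there); optional, used by the multiparametric fit
    m_gatp_ctrl_alpha: float | None = None
    sd_gatp_ctrl_alpha: float = 0.0
    m_gatp_ctrl_beta: float | None = None
    sd_gatp_ctrl_beta: float = 0.0
    m_aatp_ctrl_alpha: float | None = None
    sd_aatp_ctrl_alpha: float = 0.0
    m_aatp_ctrl_beta: float | None = None
    sd_aatp_ctrl_beta: float = 0.0
    alpha: float = 16.0
    beta: float = 64.0
    tr: float = 0.4
    sat_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("m_alpha_sat", "m_beta_sat", "m_alpha_ctrl", "m_beta_ctrl"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")

    @property
    def flip_ratio(self) -> float:
        return self.beta / self.alpha

    def amplitudes(self) -> np.ndarray:
        vals = [self.m_alpha_sat, self.m_beta_sat, self.m_alpha_ctrl, self.m_beta_ctrl]
        if self.m_unsat is not None:
            vals.append(self.m_unsat)
        return np.array(vals)

    def sds(self) -> np.ndarray:
        vals = [self.sd_alpha_sat, self.sd_beta_sat, self.sd_alpha_ctrl, self.sd_beta_ctrl]
        if self.m_unsat is not None:
            vals.append(self.sd_unsat)
        return np.array(vals)


@dataclass
class KineticResult:
    """Derived per-voxel kinetics with propagated uncertainties.

    ``sd_analytic`` holds first-order (delta-method) SDs, ``sd_mc``
    Monte-Carlo resampling SDs; both are keyed by quantity name.  ``usable``
    is False when any intermediate was non-physical, with the offending
    quantity named in ``reason``.
    """

    t1_prime: float
    t1: float
    m0_prime: float
    m0: float
    kf: float
    q: float
    sd_analytic: dict = field(default_factory=dict)
    sd_mc: dict = field(default_factory=dict)
    usable: bool = True
    reason: str = ""
    mc_n_invalid: int = 0


_QUANTITIES = ("t1_prime", "t1", "m0_prime", "m0", "kf", "q")


def _estimate_vector(amps: np.ndarray, sts: SaturationTransferSet, q_correct: bool):
    """Core Eqs on an amplitude vector [a_sat, b_sat, a_ctrl, b_ctrl(, unsat)].

    Vectorized over a leading draw axis.  Returns an array of the six
    derived quantities.
    """
    a_sat, b_sat, a_ctrl, b_ctrl = (amps[..., i] for i in range(4))
    t1p = estimate_t1_dual_angle(a_sat, b_sat, sts.alpha, sts.beta, sts.tr)
    t1 = estimate_t1_dual_angle(a_ctrl, b_ctrl, sts.alpha, sts.beta, sts.tr)
    m0p = estimate_m0_dual_angle(a_sat, b_sat, sts.alpha, sts.beta, check_tol=None)
    m0 = estimate_m0_dual_angle(a_ctrl, b_ctrl, sts.alpha, sts.beta, check_tol=None)
    if sts.m_unsat is not None:
        q = amps[..., 3] / amps[..., 4] if amps.shape[-1] > 4 else np.full_like(t1, np.nan)
        # the unsaturated scan shares the beta flip: amplitude ratio equals
        # the M0 ratio, so Q needs no relaxation correction
        if q_correct:
            m0 = m0 / q
    else:
        q = np.ones_like(np.asarray(t1, dtype=float))
    kf = (1.0 / np.asarray(t1p)) * (1.0 - np.asarray(m0p) / np.asarray(m0))
    return np.stack(
        [np.asarray(x, dtype=float) for x in (t1p, t1, m0p, m0, kf, q)], axis=-1
    )


def estimate_all(
    sts: SaturationTransferSet,
    q_correct: bool = True,
    n_draws: int = 10_000,
    seed: int | None = 0,
) -> KineticResult:
    """Full per-voxel pipeline: dual-angle T1s and M0s, Q and kf.

    Uncertainties are propagated two ways and both reported: first-order
    delta method (numeric Jacobian against the amplitude SDs) and seeded
    Monte-Carlo resampling of the amplitudes (``n_draws`` Gaussian draws;
    non-finite draws are counted, not dropped silently).

    When the unsaturated scan is present, Q is measured and (by default)
    used to correct the control M0 for direct-saturation spillover.  When it
    is absent Q defaults to 1.
    """
    amps = sts.amplitudes()
    sds = sts.sds()
    central = _estimate_vector(amps, sts, q_correct)
    t1p, t1, m0p, m0, kf, q = central

    usable = bool(np.all(np.isfinite(central)))
    reason = ""
    if not usable:
        bad = [name for name, v in zip(_QUANTITIES, central) if not np.isfinite(v)]
        reason = "non-physical intermediate: " + ", ".join(bad)

    # first-order propagation via central differences
    sd_analytic = dict.fromkeys(_QUANTITIES, np.nan)
    if usable:
        jac = np.zeros((len(amps), 6))
        for i in range(len(amps)):
            h = max(1e-7 * abs(amps[i]), 1e-12)
            up, dn = amps.copy(), amps.copy()
            up[i] += h
            dn[i] -= h
            jac[i] = (_estimate_vector(up, sts, q_correct) - _estimate_vector(dn, sts, q_correct)) / (2 * h)
        var = (sds[:, None] ** 2 * jac**2).sum(axis=0)
        sd_analytic = dict(zip(_QUANTITIES, np.sqrt(var)))

    # Monte-Carlo resampling
    sd_mc = dict.fromkeys(_QUANTITIES, np.nan)
    n_invalid = 0
    if np.any(sds > 0) and n_draws > 0:
        rng = np.random.default_rng(seed)
        draws = amps + rng.standard_normal((n_draws, len(amps))) * sds
        res = _estimate_vector(draws, sts, q_correct)
        finite = np.all(np.isfinite(res), axis=-1)
        n_invalid = int(n_draws - finite.sum())
        if finite.any():
            sd_mc = dict(zip(_QUANTITIES, res[finite].std(axis=0, ddof=1)))
    elif not np.any(sds > 0):
        sd_mc = dict.fromkeys(_QUANTITIES, 0.0)
        sd_analytic = dict.fromkeys(_QUANTITIES, 0.0) if usable else sd_analytic

    return KineticResult(
        t1_prime=float(t1p),
        t1=float(t1),
        m0_prime=float(m0p),
        m0=float(m0),
        kf=float(kf),
        q=float(q),
        sd_analytic=sd_analytic,
        sd_mc=sd_mc,
        usable=usable,
        reason=reason,
        mc_n_invalid=n_invalid,
    )


# ---------------------------------------------------------------------------
# Concentration and flux
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxResult:
    """[PCr] and CK flux derived from kf and the PCr/ATP amplitude ratio."""

    pcr_atp_ratio: float
    atp_conc: float
    pcr_conc: float
    ck_flux: float
    sd_pcr_atp_ratio: float = 0.0
    sd_atp_conc: float = 0.0
    sd_pcr_conc: float = 0.0
    sd_ck_flux: float = 0.0


def concentration_and_flux(
    kf: float,
    pcr_atp_ratio: float,
    atp_conc: float = DEFAULT_ATP_CONC,
    kf_sd: float = 0.0,
    ratio_sd: float = 0.0,
    atp_sd: float = 0.0,
) -> FluxResult:
    """[PCr] = [ATP] * M0_PCr/M0_ATP and CK flux = kf * [PCr].

    ``atp_conc`` defaults to the variance-weighted literature mean for
    myocardium (5.82 mmol/kg wet weight).  SDs combine in first order,
    treating kf and the amplitude ratio as independent.
    """
    pcr = atp_conc * pcr_atp_ratio
    flux = kf * pcr
    rel = lambda sd, x: (sd / x) ** 2 if x != 0 else 0.0
    sd_pcr = abs(pcr) * math.sqrt(rel(atp_sd, atp_conc) + rel(ratio_sd, pcr_atp_ratio))
    sd_flux = abs(flux) * math.sqrt(rel(kf_sd, kf) + rel(sd_pcr, pcr)) if flux != 0 else 0.0
    return FluxResult(
        pcr_atp_ratio=pcr_atp_ratio,
        atp_conc=atp_conc,
        pcr_conc=pcr,
        ck_flux=flux,
        sd_pcr_atp_ratio=ratio_sd,
        sd_atp_conc=atp_sd,
        sd_pcr_conc=sd_pcr,
        sd_ck_flux=sd_flux,
    )


# ---------------------------------------------------------------------------
# Literature-table summaries
# ---------------------------------------------------------------------------

def _table_frame(table) -> pd.DataFrame:
    df = pd.DataFrame(table)
    if "mean" not in df.columns:
        raise InvalidParameterError("literature table needs a 'mean' column")
    return df


def variance_weighted_mean(table) -> tuple[float, float]:
    """Inverse-variance weighted mean of study means and its SD.

    ``mean = sum(x_i / s_i^2) / sum(1 / s_i^2)``; ``sd = sqrt(1 / sum(1/s_i^2))``.
    ``table`` is anything DataFrame-like with 'mean' and 'sd' columns.
    """
    df = _table_frame(table)
    if np.any(df["sd"] <= 0):
        raise InvalidParameterError("all SDs must be positive")
    w = 1.0 / df["sd"].to_numpy() ** 2
    mean = float((w * df["mean"].to_numpy()).sum() / w.sum())
    return mean, float(math.sqrt(1.0 / w.sum()))


def n_weighted_mean(table) -> float:
    """Cohort-size weighted arithmetic mean of study means."""
    df = _table_frame(table)
    if "n" not in df.columns or np.any(df["n"] < 1):
        raise InvalidParameterError("table needs an 'n' column with n >= 1")
    n = df["n"].to_numpy(dtype=float)
    return float((n * df["mean"].to_numpy()).sum() / n.sum())


# ---------------------------------------------------------------------------
# Multiparametric Bloch-McConnell least squares
# ---------------------------------------------------------------------------

def _bm_observations(sts: SaturationTransferSet, q: float) -> list:
    """(value, sd, predictor) triples for every available amplitude.

    Predictors map theta = (m0_pcr, m0_atp, t1_pcr, t1_gatp, t1_aatp, kf)
    to the expected amplitude.  PCr amplitudes come from the exact two-pool
    propagation of the pulsed sequence (control scans scaled by the
    spillover factor q); gamma-ATP from the same system in the scans where
    it is not saturated; alpha-ATP as a non-exchanging single pool sharing
    m0_atp.
    """

    def pcr_gatp(theta, flip, mode):
        m0_pcr, m0_atp, t1_pcr, t1_gatp, _, kf = theta
        pools = PoolSystem(m0_pcr=m0_pcr, m0_atp=m0_atp, t1_pcr=t1_pcr, t1_gatp=t1_gatp, kf=kf)
        seq = SequenceParams(
            tr=sts.tr,
            flip=flip,
            saturation=mode,
            sat_fraction=sts.sat_fraction if mode == "gamma_atp" else 0.0,
        )
        return steady_state_signal(pools, seq)

    def aatp(theta, flip):
        return partial_saturation_signal(flip, sts.tr, theta[4], theta[1])

    a, b = sts.alpha, sts.beta
    obs = [
        (sts.m_alpha_sat, sts.sd_alpha_sat, lambda t: pcr_gatp(t, a, "gamma_atp")[0]),
        (sts.m_beta_sat, sts.sd_beta_sat, lambda t: pcr_gatp(t, b, "gamma_atp")[0]),
        (sts.m_alpha_ctrl, sts.sd_alpha_ctrl, lambda t: q * pcr_gatp(t, a, "none")[0]),
        (sts.m_beta_ctrl, sts.sd_beta_ctrl, lambda t: q * pcr_gatp(t, b, "none")[0]),
    ]
    optional = [
        (sts.m_unsat, sts.sd_unsat, lambda t: pcr_gatp(t, b, "none")[0]),
        (sts.m_gatp_unsat, sts.sd_gatp_unsat, lambda t: pcr_gatp(t, b, "none")[1]),
        (sts.m_aatp_unsat, sts.sd_aatp_unsat, lambda t: aatp(t, b)),
        (sts.m_gatp_ctrl_alpha, sts.sd_gatp_ctrl_alpha, lambda t: pcr_gatp(t, a, "none")[1]),
        (sts.m_gatp_ctrl_beta, sts.sd_gatp_ctrl_beta, lambda t: pcr_gatp(t, b, "none")[1]),
        (sts.m_aatp_ctrl_alpha, sts.sd_aatp_ctrl_alpha, lambda t: aatp(t, a)),
        (sts.m_aatp_ctrl_beta, sts.sd_aatp_ctrl_beta, lambda t: aatp(t, b)),
    ]
    obs.extend((v, s, f) for v, s, f in optional if v is not None)
    return obs


def fit_bloch_mcconnell(
    sts: SaturationTransferSet,
    x0: dict | None = None,
    n_starts: int = 4,
    seed: int = 0,
    spillover_q: float | None = None,
    fixed_t1_aatp: float = 2.0,
) -> dict:
    """Variance-weighted nonlinear least squares to the two-pool forward model.

    Fits (M0_PCr, M0_ATP, T1*_PCr, T1*_gATP, T1_aATP, kf) to the PCr
    amplitudes of all scans plus the gamma- and alpha-ATP amplitudes of the
    scans where they are unsaturated, minimising
    ``sum(((y - f(theta)) / sd)^2)``.  Multistart (``n_starts`` perturbed
    initialisations) guards against local minima; parameter SDs come from
    the Jacobian at the optimum (Gauss-Newton covariance with known
    per-point SDs).

    ``spillover_q`` scales the predicted control-scan PCr amplitudes; when
    None it is measured from the unsaturated scan if present, else 1.
    When alpha-ATP is observed at a single flip angle only, its T1 is not
    identifiable and is held at ``fixed_t1_aatp`` (its role is anchoring
    M0_ATP).

    Returns a dict of fitted values, SDs (``sd_<name>``), the derived
    ``pcr_atp_ratio``, ``converged`` and ``cost``.
    """
    from scipy.optimize import least_squares

    if sts.m_gatp_unsat is None or sts.m_aatp_unsat is None:
        raise InvalidParameterError(
            "multiparametric fit needs unsaturated gamma-ATP and alpha-ATP amplitudes"
        )
    if spillover_q is None:
        spillover_q = (
            compute_q(sts.m_beta_ctrl, sts.m_unsat) if sts.m_unsat else 1.0
        )
    obs = _bm_observations(sts, spillover_q)
    y = np.array([v for v, _, _ in obs])
    sd = np.array([s for _, s, _ in obs])
    w = np.where(sd > 0, 1.0 / np.where(sd > 0, sd, 1.0), 1.0)

    fit_t1_aatp = sts.m_aatp_ctrl_alpha is not None
    names = ("m0_pcr", "m0_atp", "t1_pcr", "t1_gatp", "t1_aatp", "kf")
    scale = max(float(np.max(y)), 1e-12)
    defaults = {
        "m0_pcr": 6.0 * scale,
        "m0_atp": 4.0 * scale,
        "t1_pcr": 6.0,
        "t1_gatp": 2.0,
        "t1_aatp": fixed_t1_aatp,
        "kf": 0.3,
    }
    if x0:
        defaults.update(x0)
    free = [n for n in names if fit_t1_aatp or n != "t1_aatp"]
    theta0_free = np.array([defaults[n] for n in free])
    bounds_all = {
        "m0_pcr": (1e-9, np.inf),
        "m0_atp": (1e-9, np.inf),
        "t1_pcr": (0.1, 60.0),
        "t1_gatp": (0.1, 60.0),
        "t1_aatp": (0.1, 60.0),
        "kf": (0.0, 5.0),
    }
    lo = np.array([bounds_all[n][0] for n in free])
    hi = np.array([bounds_all[n][1] for n in free])

    def expand(theta_free):
        full = dict(zip(free, theta_free))
        full.setdefault("t1_aatp", fixed_t1_aatp)
        return np.array([full[n] for n in names])

    def residuals(theta_free):
        theta = expand(theta_free)
        return (y - np.array([f(theta) for _, _, f in obs])) * w

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        start = theta0_free if k == 0 else np.clip(
            theta0_free * np.exp(rng.normal(0, 0.3, len(theta0_free))), lo + 1e-9, hi - 1e-9
        )
        try:
            res = least_squares(residuals, start, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return {"converged": False}

    out = dict(zip(names, expand(best.x)))
    jac = best.jac
    try:
        cov = np.linalg.inv(jac.T @ jac)
        sds_free = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        sds_free = np.full(len(free), np.nan)
    out.update({f"sd_{n}": s for n, s in zip(free, sds_free)})
    if not fit_t1_aatp:
        out["sd_t1_aatp"] = 0.0
    out["spillover_q"] = spillover_q
    out["pcr_atp_ratio"] = out["m0_pcr"] / out["m0_atp"]
    r = out["pcr_atp_ratio"]
    out["sd_pcr_atp_ratio"] = abs(r) * math.sqrt(
        (out["sd_m0_pcr"] / out["m0_pcr"]) ** 2 + (out["sd_m0_atp"] / out["m0_atp"]) ** 2
    )
    out["converged"] = bool(best.success)
    out["cost"] = float(best.cost)
    return out


# ---------------------------------------------------------------------------
# B1-error propagation
# ---------------------------------------------------------------------------

def propagate_b1_error(
    epsilon_b1: float,
    amplitude_cv: float,
    pools: PoolSystem | None = None,
    alpha: float = 16.0,
    beta: float = 64.0,
    tr: float = 0.4,
    n_draws: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Fractional kf bias and SD from miscalibrated flip angles and noise.

    Signals are generated at the *true* flip angles from the apparent
    single-pool forms (T1', M0' under saturation; T1*, M0 without), then
    inverted with the flip angles mis-scaled by ``(1 + epsilon_b1)`` — the
    systematic error a biased B1+ map induces.  ``amplitude_cv`` adds
    Gaussian amplitude noise (fraction of each amplitude) over ``n_draws``
    seeded draws.  Returns ``(bias, sd)`` as fractions of the true kf.
    Note the asymmetry: underestimating B1 does not mirror overestimating it.
    """
    pools = pools or PoolSystem()
    t1p, m0p_over = saturated_pool_steady_state(pools)
    m0 = pools.m0_pcr
    true_amps = np.array(
        [
            partial_saturation_signal(alpha, tr, t1p, m0p_over),
            partial_saturation_signal(beta, tr, t1p, m0p_over),
            partial_saturation_signal(alpha, tr, pools.t1_pcr, m0),
            partial_saturation_signal(beta, tr, pools.t1_pcr, m0),
        ]
    )
    a_ass, b_ass = alpha * (1.0 + epsilon_b1), beta * (1.0 + epsilon_b1)

    def invert(amps):
        t1p_e = estimate_t1_dual_angle(amps[..., 0], amps[..., 1], a_ass, b_ass, tr)
        m0p_e = estimate_m0_dual_angle(amps[..., 0], amps[..., 1], a_ass, b_ass, check_tol=None)
        m0_e = estimate_m0_dual_angle(amps[..., 2], amps[..., 3], a_ass, b_ass, check_tol=None)
        return (1.0 / np.asarray(t1p_e)) * (1.0 - np.asarray(m0p_e) / np.asarray(m0_e))

    kf_sys = invert(true_amps)
    bias = (float(kf_sys) - pools.kf) / pools.kf
    if amplitude_cv == 0:
        return bias, 0.0
    rng = np.random.default_rng(seed)
    draws = true_amps + rng.standard_normal((n_draws, 4)) * (amplitude_cv * true_amps)
    kf_draws = invert(draws)
    kf_draws = kf_draws[np.isfinite(kf_draws)]
    return bias, float(kf_draws.std(ddof=1) / pools.kf)


# ---------------------------------------------------------------------------
# Bloch-Siegert phase pair -> B1 and flip maps
# ---------------------------------------------------------------------------

def b1_map_from_phase_pair(phase_pos, phase_neg, pulse: FermiPulse):
    """gamma-B1 map (Hz) from positive/negative-offset Bloch-Siegert phases.

    The Bloch-Siegert phase is ``K_BS * gB1^2`` with the sign of the offset;
    half the phase difference divided by K_BS gives gB1^2.  Voxels with a
    negative phase difference (pure noise) are masked to NaN.
    """
    k_bs = bloch_siegert_k(pulse)
    dphi = (np.asarray(phase_pos, dtype=float) - np.asarray(phase_neg, dtype=float)) / 2.0
    with np.errstate(invalid="ignore"):
        out = np.where(dphi >= 0, np.sqrt(np.abs(dphi) / k_bs), np.nan)
    return out


def flip_map_from_b1(b1_map, target_index, target_flip: float):
    """Flip-angle map (deg) scaling linearly with B1+.

    The transmit voltage is chosen so that the voxel at ``target_index``
    receives exactly ``target_flip`` degrees; every other voxel's flip
    scales with its local B1.  Multiplying the returned map by the voltage
    ratio m = V_beta/V_alpha scales every voxel's flip by exactly m.
    """
    b1 = np.asarray(b1_map, dtype=float)
    ref = b1[tuple(np.atleast_1d(target_index))] if np.ndim(target_index) else b1[target_index]
    if not np.isfinite(ref) or ref <= 0:
        raise InvalidParameterError("target voxel has no usable B1 value")
    return target_flip * b1 / ref
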