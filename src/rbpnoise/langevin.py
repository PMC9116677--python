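"""Langevin simulation of the two-gene cascade.

Four state variables per cell — mRNA and protein of the regulator
(eBFP2-MS2CP) and of the target (sfGFP) — follow birth-death dynamics
with dilution at the growth rate μ.  The deterministic fixed point
equals the analytic means.  Three kinds of fluctuations are added, each
calibrated so the stationary protein moments reproduce the analytic
noise decomposition term by term:

* white intrinsic noise on each birth-death equation with
  propensity-style state-dependent amplitudes (√state, as in a
  square-root diffusion), which keeps the state non-negative and gives
  the skewed, Gamma-like stationary marginals expected at these noise
  levels; the protein amplitude covers the share of the Fano factor not
  already borne by mRNA fluctuations (lambda/(d_m+μ));
* one colored extrinsic process per gene injected additively at the
  translation step (a mean-zero perturbation of the synthesis flux,
  built from a mean-one lognormal of an Ornstein-Uhlenbeck process),
  whose log-variance is solved numerically so the dilution-filtered
  CV² equals the eta² plateau; additive injection keeps the three
  noise sources independent, as the analytic decomposition assumes;
* a colored LacI-activity process multiplying the regulator's
  transcription rate, likewise a mean-one lognormal OU, calibrated
  through the two-stage (mRNA + dilution) filter so the stationary
  regulation-noise term of the regulator is reproduced.

The regulator protein itself drives the target's translation rate
through the linearized slope of the repression Hill function, with the
sensed fluctuation attenuated by sqrt(gamma_y) (fluorescence-to-
molecule conversion); the target's regulation noise is therefore
emergent, not calibrated.  The linearized drive matches the analytic
model, which propagates regulator noise through the squared slope.

Integration is piecewise-deterministic: fluctuation values are frozen
over each update interval and the then-linear system is advanced with
its closed-form exponential update (translation-rate factors are
evaluated from the state at the interval start).  Colored processes
advance by their exact OU update at interval boundaries.  Negative
states are clamped to zero and counted; with the square-root
amplitudes, clamping events are rare.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .deterministic import effective_theta_x, evaluate_condition
from .noise import (cv2_regulator, d_regulator_d_iptg, d_target_d_regulator,
                    noise_params_at_growth)
from .params import (Condition, DoseResponseParams, GrowthCouplingParams,
                     NoiseParams, SimConfig)

__all__ = ["LangevinSystem", "Trajectory", "EnsembleStats",
           "build_system", "integrate", "ensemble_stats"]

#: mRNA turnover rate [h⁻¹] (few-minute bacterial mRNA half-life).
DEFAULT_MRNA_TURNOVER = 6.0
#: Mean regulator mRNA (model units) at full induction and μ0.
DEFAULT_MRNA_SCALE_X = 10.0
#: Mean target mRNA (model units): abundant constitutive transcript.
DEFAULT_MRNA_SCALE_Y = 1000.0


@dataclass(frozen=True)
class Trajectory:
    """One stochastic trajectory: times [h] and the four abundances [AU-equivalent]."""

    times: np.ndarray
    mrna_x: np.ndarray
    prot_x: np.ndarray
    mrna_y: np.ndarray
    prot_y: np.ndarray


@dataclass(frozen=True)
class EnsembleStats:
    """Pooled time-and-ensemble stationary moments per variable.

    ``mean``/``variance``/``cv2`` keyed by variable name; ``sem`` is the
    standard error of the pooled mean from between-trajectory spread.
    """

    mean: dict[str, float]
    variance: dict[str, float]
    cv2: dict[str, float]
    sem: dict[str, float]
    n_trajectories: int
    n_samples: int


@dataclass(frozen=True)
class LangevinSystem:
    """Assembled SDE system for one condition (see :func:`build_system`)."""

    condition: Condition
    dp: DoseResponseParams
    gp: GrowthCouplingParams
    mu: float
    e_mean: float
    g_mean: float
    d_m: float
    mbar_x: float          # mean regulator mRNA at the condition
    mbar_y: float          # mean target mRNA
    lam_x: float           # regulator translation rate [AU per mRNA-unit per h]
    lam_y_bar: float       # target translation rate at the fixed point
    beta_resid_x: float    # protein-level intrinsic Fano shares [AU]
    beta_resid_y: float
    eta2_x: float          # growth-scaled extrinsic CV² targets
    eta2_y: float
    reg_cv2_x: float       # analytic regulation-noise target of the regulator
    sense_slope_y: float   # d(log lam_y)/d(prot_x), gamma-attenuated [1/AU]
    noise_scale: float = 1.0

    def without_noise(self) -> "LangevinSystem":
        """Copy with every fluctuation amplitude set to zero."""
        return replace(self, noise_scale=0.0)


def _two_stage_overlap(u: np.ndarray, a: float, b: float) -> np.ndarray:
    """Overlap ∫g(s)g(s+u)ds of the two-stage filter kernel.

    g is the unit-static-gain impulse response of two first-order
    stages with rates ``a`` and ``b`` in series.
    """
    if abs(a - b) < 1e-9 * a:
        b = a * (1.0 + 1e-6)
    c = a * b / (b - a)
    return c**2 * (np.exp(-a * u) / (2 * a) + np.exp(-b * u) / (2 * b)
                   - (np.exp(-a * u) + np.exp(-b * u)) / (a + b))


def _single_stage_overlap(u: np.ndarray, a: float) -> np.ndarray:
    return 0.5 * a * np.exp(-a * u)


def _lognormal_ou_sigma2(target_var: float, theta: float,
                         stage_rates: tuple[float, ...]) -> float:
    """Log-variance of a mean-one lognormal-OU flux factor.

    Solves for sigma² such that exp(OU) − 1, with OU correlation rate
    ``theta`` and log-variance sigma², produces stationary relative
    variance ``target_var`` after passing through the first-order
    filter chain ``stage_rates``.  The flux autocovariance is
    exp(sigma²·e^{−theta·u}) − 1.
    """
    if target_var <= 0:
        return 0.0
    slowest = min((theta,) + stage_rates)
    u = np.linspace(0.0, 40.0 / slowest, 4001)
    if len(stage_rates) == 1:
        k = _single_stage_overlap(u, stage_rates[0])
    elif len(stage_rates) == 2:
        k = _two_stage_overlap(u, *stage_rates)
    else:
        raise ValueError("supported filter chains: one or two stages")
    rho = np.exp(-theta * u)

    def filtered_var(s2: float) -> float:
        return float(2.0 * np.trapezoid(k * (np.exp(s2 * rho) - 1.0), u))

    hi = 1.0
    while filtered_var(hi) < target_var:
        hi *= 2.0
        if hi > 64.0:
            raise ValueError("colored-noise target variance unattainably large")
    return float(brentq(lambda s2: filtered_var(s2) - target_var, 0.0, hi,
                        xtol=1e-12))


def build_system(c: Condition, dp: DoseResponseParams, gp: GrowthCouplingParams,
                 npar: NoiseParams, d_m: float = DEFAULT_MRNA_TURNOVER,
                 m_scale_x: float = DEFAULT_MRNA_SCALE_X,
                 m_scale_y: float = DEFAULT_MRNA_SCALE_Y) -> LangevinSystem:
    """Assemble the four-variable Langevin system for one condition.

    Transcription is proportional to μ and (for the regulator) to the
    LacI-IPTG Hill factor; translation rates are fixed by requiring the
    deterministic fixed point to equal the analytic means.  White-noise
    amplitudes are calibrated so the stationary protein Fano factors
    reproduce the growth-scaled beta constants; the mRNA-borne share
    lambda/(d_m+μ) must not exceed beta, otherwise the requested mRNA
    scale is inconsistent with the noise constants and a ValueError is
    raised (use a larger ``m_scale``).
    """
    if d_m <= 0 or m_scale_x <= 0 or m_scale_y <= 0:
        raise ValueError("d_m and mRNA scales must be positive")
    st = evaluate_condition(c, dp, gp)
    mu = st.mu
    nmu = noise_params_at_growth(npar, mu, gp)

    u = (c.iptg / dp.theta_i) ** dp.n_i
    hill_x = (dp.rho_x + u) / (1.0 + u)
    mbar_x = m_scale_x * hill_x * (mu / gp.mu0)   # transcription ∝ μ
    mbar_y = m_scale_y * (mu / gp.mu0)
    lam_x = st.e_mean * mu / mbar_x
    lam_y = st.g_mean * mu / mbar_y

    fano_from_mrna_x = lam_x / (d_m + mu)
    fano_from_mrna_y = lam_y / (d_m + mu)
    for name, fano, beta in (("regulator", fano_from_mrna_x, nmu.beta_x),
                             ("target", fano_from_mrna_y, nmu.beta_y)):
        if fano > beta:
            raise ValueError(
                f"inconsistent parameters: {name} mRNA-borne Fano factor "
                f"{fano:.3g} AU exceeds beta {beta:.3g} AU; increase the mRNA scale")

    # regulation-noise target of the regulator (analytic, post-filter)
    slope_e = d_regulator_d_iptg(c.iptg, dp, gp, mu)
    reg_cv2_x = 0.5 * slope_e**2 * nmu.eta2_lac / st.e_mean**2

    # gamma-attenuated log-slope of the target's sensed repression
    hill_slope = d_target_d_regulator(st.e_mean, dp, gp, mu)
    sense_slope_y = math.sqrt(npar.gamma_y) * hill_slope / st.g_mean

    return LangevinSystem(
        condition=c, dp=dp, gp=gp, mu=mu, e_mean=st.e_mean, g_mean=st.g_mean,
        d_m=d_m, mbar_x=mbar_x, mbar_y=mbar_y, lam_x=lam_x, lam_y_bar=lam_y,
        beta_resid_x=nmu.beta_x - fano_from_mrna_x,
        beta_resid_y=nmu.beta_y - fano_from_mrna_y,
        eta2_x=nmu.eta2_x, eta2_y=nmu.eta2_y, reg_cv2_x=reg_cv2_x,
        sense_slope_y=sense_slope_y,
    )


def integrate(system: LangevinSystem, cfg: SimConfig,
              initial: str = "stationary", record_every: int = 10,
              clamp_warn_fraction: float = 1e-3) -> list[Trajectory]:
    """Integrate the system into ``cfg.n_trajectories`` trajectories.

    Within each ``update_interval`` the fluctuation values (white draws,
    colored flux factors, and the target translation rate) are frozen
    and the linear system advanced by its exact exponential update; at
    interval boundaries white terms are redrawn with amplitudes from
    the current state and OU processes advanced by their exact update.
    ``initial`` is ``"stationary"`` (start at the deterministic fixed
    point) or ``"uninduced"`` (start at the IPTG=0 fixed point, e.g. to
    watch the sigmoidal rise after induction).  Each trajectory
    consumes an independent child stream of ``cfg.seed``, so earlier
    trajectories are unchanged when ``n_trajectories`` grows.  Fully
    reproducible from the seed.
    """
    s, mu, d_m = system, system.mu, system.d_m
    dt = cfg.update_interval
    n_steps = int(round(cfg.horizon / dt))
    tau = cfg.tau_ext if cfg.tau_ext is not None else 1.0 / mu
    theta = 1.0 / tau
    ns = s.noise_scale

    # log-variances of the mean-one lognormal flux factors, solved so the
    # filtered stationary CV² contributions equal the analytic terms
    s2_ext_x = _lognormal_ou_sigma2(s.eta2_x * ns**2, theta, (mu,))
    s2_ext_y = _lognormal_ou_sigma2(s.eta2_y * ns**2, theta, (mu,))
    s2_lac = _lognormal_ou_sigma2(s.reg_cv2_x * ns**2, theta, (d_m, mu))

    rho_ou = math.exp(-dt / tau)
    ou_kick = math.sqrt(1.0 - rho_ou**2)
    inv_sqrt_dt = 1.0 / math.sqrt(dt)
    # propensity-style state-dependent white amplitudes: rate-variance
    # coefficients multiplying the instantaneous state
    c_m = math.sqrt(2.0 * d_m) * inv_sqrt_dt * ns
    c_p_x = math.sqrt(2.0 * mu * max(s.beta_resid_x, 0.0)) * inv_sqrt_dt * ns
    c_p_y = math.sqrt(2.0 * mu * max(s.beta_resid_y, 0.0)) * inv_sqrt_dt * ns

    n_traj = cfg.n_trajectories
    children = np.random.SeedSequence(cfg.seed).spawn(n_traj)
    # Per-trajectory independent streams, stacked for vectorized stepping.
    draws = np.stack([np.random.default_rng(ss).standard_normal((n_steps, 7))
                      for ss in children], axis=1)  # (n_steps, n_traj, 7)

    if initial == "stationary":
        m_x0, p_x0, m_y0, p_y0 = s.mbar_x, s.e_mean, s.mbar_y, s.g_mean
    elif initial == "uninduced":
        st0 = evaluate_condition(Condition(iptg=0.0, tc=s.condition.tc), s.dp, s.gp)
        u0 = 0.0
        hill0 = (s.dp.rho_x + u0) / (1.0 + u0)
        u1 = (s.condition.iptg / s.dp.theta_i) ** s.dp.n_i
        hill1 = (s.dp.rho_x + u1) / (1.0 + u1)
        m_x0 = s.mbar_x * hill0 / hill1
        p_x0, m_y0, p_y0 = st0.e_mean, s.mbar_y, st0.g_mean
    else:
        raise ValueError(f"unknown initial state {initial!r}")

    m_x = np.full(n_traj, float(m_x0))
    p_x = np.full(n_traj, float(p_x0))
    m_y = np.full(n_traj, float(m_y0))
    p_y = np.full(n_traj, float(p_y0))
    zeta = np.zeros(n_traj)     # unit-variance OU states
    eps_x = np.zeros(n_traj)
    eps_y = np.zeros(n_traj)

    e_md = math.exp(-d_m * dt)
    e_mu = math.exp(-mu * dt)
    sd_lac, sd_ex, sd_ey = math.sqrt(s2_lac), math.sqrt(s2_ext_x), math.sqrt(s2_ext_y)

    n_rec = n_steps // record_every
    rec = np.empty((n_rec, 4, n_traj))
    rec_t = np.empty(n_rec)
    clamps = 0

    for k in range(n_steps):
        z = draws[k]
        # advance colored processes (exact OU update, unit variance)
        zeta = zeta * rho_ou + ou_kick * z[:, 0]
        eps_x = eps_x * rho_ou + ou_kick * z[:, 1]
        eps_y = eps_y * rho_ou + ou_kick * z[:, 2]
        flux_lac = np.exp(sd_lac * zeta - 0.5 * s2_lac)
        flux_ext_x = np.exp(sd_ex * eps_x - 0.5 * s2_ext_x)
        flux_ext_y = np.exp(sd_ey * eps_y - 0.5 * s2_ext_y)

        # frozen sources over this interval; the extrinsic factors enter
        # the protein equations additively (mean-zero flux perturbation
        # around the stationary synthesis flux μ·⟨p⟩) so the three noise
        # sources stay independent, as the analytic decomposition assumes
        src_m_x = d_m * s.mbar_x * flux_lac + c_m * np.sqrt(m_x) * z[:, 3]
        src_m_y = d_m * s.mbar_y + c_m * np.sqrt(m_y) * z[:, 4]
        b_p_x = mu * s.e_mean * (flux_ext_x - 1.0) + c_p_x * np.sqrt(p_x) * z[:, 5]
        b_p_y = mu * s.g_mean * (flux_ext_y - 1.0) + c_p_y * np.sqrt(p_y) * z[:, 6]
        lam_x = s.lam_x
        # linearized, gamma-attenuated repression drive, frozen at the
        # interval start; clipped at zero (full repression)
        lam_y = s.lam_y_bar * np.maximum(
            1.0 + ns * s.sense_slope_y * (p_x - s.e_mean), 0.0)

        # exact update of the frozen linear system
        ms_x = src_m_x / d_m
        ms_y = src_m_y / d_m
        cc_x = lam_x * (m_x - ms_x) / (mu - d_m)
        cc_y = lam_y * (m_y - ms_y) / (mu - d_m)
        ps_x = (lam_x * ms_x + b_p_x) / mu
        ps_y = (lam_y * ms_y + b_p_y) / mu
        p_x = ps_x + (p_x - ps_x - cc_x) * e_mu + cc_x * e_md
        p_y = ps_y + (p_y - ps_y - cc_y) * e_mu + cc_y * e_md
        m_x = ms_x + (m_x - ms_x) * e_md
        m_y = ms_y + (m_y - ms_y) * e_md

        neg = (m_x < 0) | (p_x < 0) | (m_y < 0) | (p_y < 0)
        if neg.any():
            clamps += int((m_x < 0).sum() + (p_x < 0).sum()
                          + (m_y < 0).sum() + (p_y < 0).sum())
            np.maximum(m_x, 0.0, out=m_x)
            np.maximum(p_x, 0.0, out=p_x)
            np.maximum(m_y, 0.0, out=m_y)
            np.maximum(p_y, 0.0, out=p_y)
        if not (np.all(np.isfinite(p_x)) and np.all(np.isfinite(p_y))):
            raise RuntimeError(
                f"non-finite state at t={k * dt:.3f} h; check parameters "
                "and update_interval")

        if (k + 1) % record_every == 0:
            j = (k + 1) // record_every - 1
            rec_t[j] = (k + 1) * dt
            rec[j, 0] = m_x
            rec[j, 1] = p_x
            rec[j, 2] = m_y
            rec[j, 3] = p_y

    frac = clamps / (4.0 * n_steps * n_traj)
    if frac > clamp_warn_fraction:
        warnings.warn(f"negative-state clamping in {frac:.2%} of updates "
                      "(> 0.1%); stationary moments may be biased",
                      RuntimeWarning, stacklevel=2)

    return [Trajectory(times=rec_t.copy(), mrna_x=rec[:, 0, i].copy(),
                       prot_x=rec[:, 1, i].copy(), mrna_y=rec[:, 2, i].copy(),
                       prot_y=rec[:, 3, i].copy())
            for i in range(n_traj)]


def ensemble_stats(trajs: list[Trajectory], burn_in: float) -> EnsembleStats:
    """Pooled stationary moments over time and trajectories after ``burn_in`` [h].

    The standard error of each pooled mean is estimated from the
    between-trajectory spread of per-trajectory time averages (samples
    within a trajectory are correlated over ~1/μ, so the naive pooled
    SE would be optimistic).
    """
    if not trajs:
        raise ValueError("no trajectories supplied")
    keep = trajs[0].times > burn_in
    if keep.sum() < 10:
        raise ValueError(
            f"only {int(keep.sum())} post-burn-in samples per trajectory; "
            "reduce burn_in or extend horizon")
    mean, var, cv2, sem = {}, {}, {}, {}
    for name in ("mrna_x", "prot_x", "mrna_y", "prot_y"):
        per_traj = np.stack([getattr(t, name)[keep] for t in trajs])
        pooled = per_traj.ravel()
        m = float(pooled.mean())
        v = float(pooled.var(ddof=1))
        mean[name], var[name] = m, v
        cv2[name] = v / m**2 if m > 0 else math.nan
        traj_means = per_traj.mean(axis=1)
        sem[name] = (float(traj_means.std(ddof=1) / math.sqrt(len(trajs)))
                     if len(trajs) > 1 else math.nan)
    return EnsembleStats(mean=mean, variance=var, cv2=cv2, sem=sem,
                         n_trajectories=len(trajs), n_samples=int(keep.sum()))
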