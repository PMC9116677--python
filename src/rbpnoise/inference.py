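"""Estimation chain: event summaries, growth rates, and nonlinear fits.

Mirrors how the circuit was characterized: background subtraction and
robust outlier removal on single-cell fluorescence tables; mean,
variance and CV² per condition; growth rate as the log-absorbance slope
over an auto-detected exponential window; then sequential least-squares
fits — Michaelis-Menten growth inhibition, the two Hill-Langmuir
transfer functions, the six-constant noise decomposition, Gamma
distributions, translation-scaling constants and the volume exponent.

Hill fits are multimodal, so every nonlinear fit uses a deterministic
multistart grid (log-spaced half-saturation constants × a small set of
cooperativities) and keeps the best converged solution.  Mean fits are
weighted by 1/mean (multiplicative error structure); CV² fits are
unweighted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .noise import d_regulator_d_iptg, d_target_d_regulator
from .params import (DoseResponseParams, GammaParams, GrowthCouplingParams,
                     NoiseParams)

__all__ = [
    "FitResult",
    "subtract_autofluorescence",
    "remove_outliers",
    "summarize",
    "estimate_growth_rate",
    "fit_growth_mm",
    "fit_regulator_hill",
    "fit_target_hill",
    "fit_noise_params",
    "fit_gamma",
    "fit_epsilons",
    "fit_delta",
]

CHANNELS = ("ebfp2_au", "sfgfp_au")


@dataclass
class FitResult:
    """Outcome of one least-squares fit.

    ``params`` map estimate names to values, ``stderr`` to local-
    curvature uncertainties (NaN when unavailable); ``flags`` collect
    identifiability warnings (boundary-stuck, diverging, wide-CI).
    """

    params: dict[str, float]
    stderr: dict[str, float]
    residual_norm: float
    converged: bool
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------- events

def subtract_autofluorescence(events: pd.DataFrame,
                              blank_mean: dict[str, float]) -> pd.DataFrame:
    """Shift each channel by its blank mean (autofluorescence background).

    Values may become negative and are kept (unbiased moments).  The
    returned table is tagged so a second subtraction raises.
    """
    if events.attrs.get("background_corrected"):
        raise ValueError("events are already background-corrected")
    out = events.copy()
    for ch, m in blank_mean.items():
        if ch not in out.columns:
            raise KeyError(f"unknown channel {ch!r}")
        if not math.isfinite(m):
            raise ValueError(f"blank mean for {ch!r} must be finite")
        out[ch] = out[ch] - m
    out.attrs["background_corrected"] = True
    return out


def remove_outliers(values: np.ndarray,
                    n_mad: float = 5.0) -> tuple[np.ndarray, int]:
    """Drop values outside median ± ``n_mad``·MAD (Gaussian-scaled).

    Robust and parameter-free; at the circuit's CV² range the genuine
    heavy Gamma tail survives a 5-MAD fence.  A zero MAD (constant
    vector) removes nothing.  Requires >= 20 values.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 20:
        raise ValueError(f"need >= 20 values, got {values.size}")
    med = np.median(values)
    mad = stats.median_abs_deviation(values, scale="normal")
    if mad == 0.0:
        return values, 0
    keep = np.abs(values - med) <= n_mad * mad
    return values[keep], int((~keep).sum())


def summarize(events: pd.DataFrame, per_replicate: bool = False,
              n_mad: float = 5.0) -> pd.DataFrame:
    """Per-condition channel moments after outlier removal.

    Returns one row per condition (per replicate too when
    ``per_replicate``), with columns ``n_events``, then per channel
    ``mean_*``, ``var_*``, ``cv2_*`` and ``n_removed_*``.  CV² =
    variance/mean² is scale-free.
    """
    if events.empty:
        raise ValueError("empty event table")
    keys = ["iptg_uM", "tc_ng_mL"] + (["replicate"] if per_replicate else [])
    rows = []
    for key, grp in events.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(keys, key))
        row["n_events"] = len(grp)
        for ch in CHANNELS:
            name = ch.removesuffix("_au")
            vals, removed = remove_outliers(grp[ch].to_numpy(), n_mad=n_mad)
            m = float(vals.mean())
            v = float(vals.var(ddof=1))
            row[f"mean_{name}"] = m
            row[f"var_{name}"] = v
            row[f"cv2_{name}"] = v / m**2 if m != 0 else math.nan
            row[f"n_removed_{name}"] = removed
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- growth

def estimate_growth_rate(curve: pd.DataFrame, r2_min: float = 0.99,
                         min_points: int = 4,
                         window: tuple[float, float] | None = None) -> float:
    """Log-absorbance slope over the exponential window [h⁻¹].

    The window is the longest contiguous run of >= ``min_points``
    measurements whose log-OD/time regression reaches R² >=
    ``r2_min`` (stationary-phase points fail this and drop out);
    ``window`` overrides auto-detection with explicit (t_lo, t_hi).
    """
    t = curve["time_h"].to_numpy(dtype=float)
    od = curve["od600"].to_numpy(dtype=float)
    if np.any(od <= 0):
        raise ValueError("absorbance must be positive")
    if t.size < min_points:
        raise ValueError(f"need >= {min_points} time points, got {t.size}")
    y = np.log(od)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if mask.sum() < 2:
            raise ValueError("manual window contains fewer than 2 points")
        return float(np.polyfit(t[mask], y[mask], 1)[0])

    best: tuple[int, float, float] | None = None  # (length, r2, slope)
    n = t.size
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            ts, ys = t[i:j], y[i:j]
            slope, intercept = np.polyfit(ts, ys, 1)
            resid = ys - (slope * ts + intercept)
            ss_res = float(resid @ resid)
            ss_tot = float(((ys - ys.mean()) ** 2).sum())
            if ss_tot < 1e-12:          # flat segment: no growth signal
                continue
            r2 = 1.0 - ss_res / ss_tot
            if r2 >= r2_min:
                cand = (j - i, r2, float(slope))
                if best is None or cand[:2] > best[:2]:
                    best = cand
    if best is None:
        raise ValueError(
            f"no contiguous window of >= {min_points} points reaches "
            f"R² >= {r2_min}; not an exponential-phase curve")
    return best[2]


# ------------------------------------------------------------------ fits

def _harvest(result: lmfit.minimizer.MinimizerResult | lmfit.model.ModelResult,
             names: Sequence[str]) -> FitResult:
    params = {k: float(result.params[k].value) for k in names}
    stderr = {k: (float(result.params[k].stderr)
                  if result.params[k].stderr is not None else math.nan)
              for k in names}
    resid = np.asarray(result.residual, dtype=float)
    fr = FitResult(params=params, stderr=stderr,
                   residual_norm=float(np.sqrt(resid @ resid)),
                   converged=bool(result.success))
    for k in names:
        p = result.params[k]
        span = (p.max - p.min) if np.isfinite(p.max) and np.isfinite(p.min) else None
        for bound in (p.min, p.max):
            if np.isfinite(bound) and bound != 0 and \
                    abs(p.value - bound) < 1e-3 * max(abs(bound), 1e-12):
                fr.flags.append(f"{k}_at_boundary")
        if math.isfinite(stderr[k]) and abs(params[k]) > 0 and \
                stderr[k] > abs(params[k]):
            fr.flags.append(f"{k}_wide_uncertainty")
    return fr


def _multistart(residual, make_params, starts) -> lmfit.minimizer.MinimizerResult:
    best = None
    for start in starts:
        try:
            res = lmfit.minimize(residual, make_params(**start), method="leastsq")
        except Exception:
            continue
        cost = float(np.sum(np.asarray(res.residual) ** 2))
        if best is None or cost < best[0]:
            best = (cost, res)
    if best is None:
        raise RuntimeError("no multistart converged")
    return best[1]


def fit_growth_mm(tc: Sequence[float], rates: Sequence[float]) -> FitResult:
    """Fit μ(TC) = μ0/(1 + TC/θc) to per-TC growth rates.

    Requires >= 4 distinct TC levels.  A flat profile makes θc diverge;
    the result is then flagged ``theta_c_unidentified`` instead of
    failing.
    """
    tc = np.asarray(tc, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if np.unique(tc).size < 4:
        raise ValueError("need >= 4 distinct TC levels")

    def residual(p):
        return rates - p["mu0"] / (1.0 + tc / p["theta_c"])

    tc_pos = tc[tc > 0]
    span = (tc_pos.min(), tc_pos.max()) if tc_pos.size else (1.0, 1000.0)

    def make_params(theta_c):
        p = lmfit.Parameters()
        p.add("mu0", value=float(rates.max()), min=1e-6)
        p.add("theta_c", value=theta_c, min=1e-3, max=1e7)
        return p

    starts = [dict(theta_c=v) for v in np.geomspace(span[0], 100 * span[1], 7)]
    fr = _harvest(_multistart(residual, make_params, starts), ["mu0", "theta_c"])
    if fr.params["theta_c"] > 50 * span[1]:
        fr.flags.append("theta_c_unidentified")
    return fr


_HILL_N_STARTS = (1.0, 2.0, 3.0, 5.0, 8.0)


def fit_regulator_hill(iptg: Sequence[float], e_means: Sequence[float],
                       weights: str = "inv_mean") -> FitResult:
    """Fit the activating Hill-Langmuir dose response of the regulator.

    Estimates alpha_x, rho_x, theta_i, n_i from (IPTG, mean) pairs;
    needs >= 6 IPTG levels spanning the transition.  Replicate rows may
    share IPTG values.  ``weights='inv_mean'`` divides residuals by the
    observed mean (multiplicative errors); ``'none'`` fits raw.
    """
    iptg = np.asarray(iptg, dtype=float)
    e = np.asarray(e_means, dtype=float)
    if np.unique(iptg).size < 6:
        raise ValueError("need >= 6 distinct IPTG levels")
    w = 1.0 / e if weights == "inv_mean" else np.ones_like(e)

    def residual(p):
        u = (iptg / p["theta_i"]) ** p["n_i"]
        model = p["alpha_x"] * (p["rho_x"] + u) / (1.0 + u)
        return (e - model) * w

    pos = iptg[iptg > 0]

    def make_params(theta_i, n_i):
        p = lmfit.Parameters()
        p.add("alpha_x", value=float(e.max()), min=1e-9)
        p.add("rho_x", value=float(np.clip(e.min() / e.max(), 1e-4, 0.9)),
              min=1e-6, max=0.999)
        p.add("theta_i", value=theta_i, min=1e-6)
        p.add("n_i", value=n_i, min=0.2, max=12.0)
        return p

    starts = [dict(theta_i=t, n_i=n)
              for t in np.geomspace(pos.min(), pos.max(), 5)
              for n in _HILL_N_STARTS]
    fr = _harvest(_multistart(residual, make_params, starts),
                  ["alpha_x", "rho_x", "theta_i", "n_i"])
    if iptg.min() > 0.2 * fr.params["theta_i"]:
        fr.flags.append("rho_x_poorly_constrained")
    return fr


def fit_target_hill(e_means: Sequence[float], g_means: Sequence[float],
                    weights: str = "inv_mean") -> FitResult:
    """Fit the repressing Hill transfer function of the target.

    Regresses target means on regulator means; estimates alpha_y,
    rho_y, theta_x, n_x.  Flags n_x as unidentifiable when the
    regulator range does not cross the fitted theta_x.
    """
    e = np.asarray(e_means, dtype=float)
    g = np.asarray(g_means, dtype=float)
    if np.unique(e).size < 6:
        raise ValueError("need >= 6 distinct regulator levels")
    w = 1.0 / g if weights == "inv_mean" else np.ones_like(g)

    def residual(p):
        v = (e / p["theta_x"]) ** p["n_x"]
        model = p["alpha_y"] * (1.0 + p["rho_y"] * v) / (1.0 + v)
        return (g - model) * w

    def make_params(theta_x, n_x):
        p = lmfit.Parameters()
        p.add("alpha_y", value=float(g.max()), min=1e-9)
        p.add("rho_y", value=float(np.clip(g.min() / g.max(), 1e-5, 0.9)),
              min=1e-7, max=0.999)
        p.add("theta_x", value=theta_x, min=1e-6)
        p.add("n_x", value=n_x, min=0.2, max=12.0)
        return p

    starts = [dict(theta_x=t, n_x=n)
              for t in np.geomspace(e.min(), e.max(), 5)
              for n in _HILL_N_STARTS]
    fr = _harvest(_multistart(residual, make_params, starts),
                  ["alpha_y", "rho_y", "theta_x", "n_x"])
    th = fr.params["theta_x"]
    if not (e.min() <= th <= e.max()):
        fr.flags.append("n_x_unidentified")
    return fr


def fit_noise_params(iptg: Sequence[float], cv2_e: Sequence[float],
                     dp: DoseResponseParams, gp: GrowthCouplingParams,
                     cv2_g: Sequence[float] | None = None,
                     mu: float | None = None) -> FitResult:
    """Fit the noise constants of the analytic CV² decomposition.

    With the deterministic parameters held fixed, fits (eta2_x, beta_x,
    eta2_lac) to the regulator CV² profile and — when ``cv2_g`` is
    given — jointly (eta2_y, beta_y, gamma_y) to the target profile
    over the same IPTG levels.  Unweighted residuals; non-negativity
    enforced by bounds.  Target-channel constants are absent from the
    result when no target data is supplied.
    """
    iptg = np.asarray(iptg, dtype=float)
    cv2_e = np.asarray(cv2_e, dtype=float)
    if np.unique(iptg).size < 6:
        raise ValueError("need >= 6 distinct IPTG levels")
    mu = gp.mu0 if mu is None else mu
    from .deterministic import mean_regulator, mean_target  # late: avoid cycle
    e = np.asarray(mean_regulator(iptg, dp, gp, mu), dtype=float)
    slope_e = np.array([d_regulator_d_iptg(i, dp, gp, mu) for i in iptg])
    both = cv2_g is not None
    if both:
        cv2_g = np.asarray(cv2_g, dtype=float)
        g = np.asarray(mean_target(e, dp, gp, mu), dtype=float)
        slope_g = np.array([d_target_d_regulator(ei, dp, gp, mu) for ei in e])

    def model_e(p):
        return (p["eta2_x"] + p["beta_x"] / e
                + 0.5 * slope_e**2 * p["eta2_lac"] / e**2)

    def residual(p):
        r = cv2_e - model_e(p)
        if both:
            rg = cv2_g - (p["eta2_y"] + p["beta_y"] / g
                          + 0.5 * slope_g**2 * p["gamma_y"] * e**2 / g**2
                          * model_e(p))
            r = np.concatenate([r, rg])
        return r

    def make_params(scale):
        p = lmfit.Parameters()
        p.add("eta2_x", value=0.5 * float(cv2_e.min()) * scale, min=0.0)
        p.add("beta_x", value=float(cv2_e[0] * e[0]) * scale, min=0.0)
        p.add("eta2_lac", value=float(np.median(iptg[iptg > 0]) ** 2) * scale,
              min=0.0)
        if both:
            p.add("eta2_y", value=0.5 * float(cv2_g.min()) * scale, min=0.0)
            p.add("beta_y", value=float(cv2_g[0] * g[0]) * scale, min=0.0)
            p.add("gamma_y", value=0.02 * scale, min=0.0)
        return p

    names = ["eta2_x", "beta_x", "eta2_lac"] + \
            (["eta2_y", "beta_y", "gamma_y"] if both else [])
    starts = [dict(scale=s) for s in (0.3, 1.0, 3.0)]
    return _harvest(_multistart(residual, make_params, starts), names)


def fit_gamma(values: np.ndarray, method: str = "moments") -> GammaParams:
    """Fit a Gamma law to positive single-cell values.

    Method of moments matches the mesoscopic parameterization
    (shape = mean²/variance = 1/CV², scale = variance/mean);
    ``method='mle'`` refines by maximum likelihood with the origin
    fixed at zero.  Requires >= 100 positive values.
    """
    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    if values.size < 100:
        raise ValueError(f"need >= 100 positive values, got {values.size}")
    m = float(values.mean())
    v = float(values.var(ddof=1))
    if m <= 0 or v <= 0:
        raise ValueError("mean and variance must be positive")
    if method == "moments":
        return GammaParams(shape=m * m / v, scale=v / m)
    if method == "mle":
        a, _, b = stats.gamma.fit(values, floc=0.0)
        return GammaParams(shape=float(a), scale=float(b))
    raise ValueError(f"unknown method {method!r}")


def fit_epsilons(mu: Sequence[float], rel_sr: Sequence[float],
                 mu0: float) -> FitResult:
    """Fit the translation-scaling constants from a relative SR curve.

    Model: SR(μ)/SR(μ0) = [(eps1-μ)/(eps2-μ)] / [(eps1-μ0)/(eps2-μ0)]
    · (μ/μ0), with eps1 < eps2 < min(μ) enforced through bounds and a
    positive-gap parameterization.  Requires >= 4 μ levels.
    """
    mu = np.asarray(mu, dtype=float)
    r = np.asarray(rel_sr, dtype=float)
    if np.unique(mu).size < 4:
        raise ValueError("need >= 4 distinct mu levels")
    mu_min = float(mu.min())

    def residual(p):
        e1 = p["eps1"].value
        e2 = e1 + p["d_eps"].value
        scale = ((e1 - mu) / (e2 - mu)) / ((e1 - mu0) / (e2 - mu0))
        return r - scale * mu / mu0

    def make_params(eps1, d_eps):
        p = lmfit.Parameters()
        p.add("eps1", value=eps1, min=1e-4, max=mu_min - 0.03)
        p.add("d_eps", value=d_eps, min=1e-4, max=mu_min - 0.02)
        return p

    starts = [dict(eps1=e1, d_eps=d)
              for e1 in np.linspace(0.05, mu_min - 0.1, 4)
              for d in (0.02, 0.05, 0.1, 0.2)]
    res = _multistart(residual, make_params, starts)
    fr = _harvest(res, ["eps1", "d_eps"])
    e1 = fr.params.pop("eps1")
    d = fr.params.pop("d_eps")
    fr.params.update(eps1=e1, eps2=e1 + d)
    s1, s2 = fr.stderr.pop("eps1"), fr.stderr.pop("d_eps")
    fr.stderr.update(eps1=s1, eps2=math.hypot(s1, s2)
                     if math.isfinite(s1) and math.isfinite(s2) else math.nan)
    return fr


def fit_delta(mu: Sequence[float], median_fsc3: Sequence[float],
              mu0: float) -> FitResult:
    """Fit the volume exponent from the cubed forward-scatter medians.

    Regression of log(median fsc³) on (μ0 − μ): the slope is delta [h]
    and the intercept the log baseline volume.  Requires >= 4 μ levels.
    """
    mu = np.asarray(mu, dtype=float)
    f3 = np.asarray(median_fsc3, dtype=float)
    if np.unique(mu).size < 4:
        raise ValueError("need >= 4 distinct mu levels")
    if np.any(f3 <= 0):
        raise ValueError("median fsc³ must be positive")
    x = mu0 - mu
    y = np.log(f3)
    A = np.column_stack([x, np.ones_like(x)])
    coef, res_ss, *_ = np.linalg.lstsq(A, y, rcond=None)
    n = x.size
    dof = n - 2
    s2 = float(res_ss[0]) / dof if res_ss.size and dof > 0 else 0.0
    cov = s2 * np.linalg.inv(A.T @ A)
    resid = y - A @ coef
    return FitResult(
        params={"delta": float(coef[0]), "log_baseline": float(coef[1])},
        stderr={"delta": float(np.sqrt(cov[0, 0])),
                "log_baseline": float(np.sqrt(cov[1, 1]))},
        residual_norm=float(np.sqrt(resid @ resid)),
        converged=True,
    )
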