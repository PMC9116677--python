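"""Deterministic model of the translation-factor cascade.

Mean expressions follow Hill-Langmuir transfer functions: IPTG relieves
LacI repression of the regulator (eBFP2-MS2CP), and the regulator
represses translation of the target (sfGFP) through its RNA motif.
Growth rate μ, set by tetracycline through a Michaelis-Menten
inhibition, couples back into expression three ways:

* transcription scales with μ, cancelling against dilution in protein
  amounts per cell;
* the translation rate of gene *i* scales as (eps1_i-μ)/(eps2_i-μ), a
  reciprocal form reflecting ribosome over-production under sublethal
  translation inhibitors — maximal expression alpha_i picks up this
  factor relative to μ0;
* cell volume grows as μ drops, so the regulator-motif dissociation
  constant theta_x is corrected by exp(delta·(μ0-μ)).

Protein synthesis rates are SR = mean × μ (stable proteins).
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .params import (Condition, DoseResponseParams, GrowthCouplingParams,
                     MeanState, NoiseParams)

__all__ = [
    "growth_rate",
    "translation_scale",
    "effective_theta_x",
    "mean_regulator",
    "mean_target",
    "regulator_limits",
    "target_limits",
    "evaluate_condition",
    "dose_response_table",
    "relative_sr_curve",
    "locate_extremum",
    "BoundaryExtremumError",
    "sensitivity_scan",
    "MU_POLE_MARGIN",
]

#: Safety margin above the translation-scale pole at μ = eps2.
MU_POLE_MARGIN = 0.01

ArrayLike = Union[float, np.ndarray]


def growth_rate(tc: ArrayLike, gp: GrowthCouplingParams) -> ArrayLike:
    """Growth rate μ(TC) = μ0 / (1 + TC/θc)  [h⁻¹].

    Michaelis-Menten inhibition by tetracycline; μ(0) = μ0 and
    μ(θc) = μ0/2 exactly.
    """
    tc = np.asarray(tc, dtype=float)
    if np.any(tc < 0) or not np.all(np.isfinite(tc)):
        raise ValueError("tc must be finite and non-negative")
    out = gp.mu0 / (1.0 + tc / gp.theta_c)
    return float(out) if out.ndim == 0 else out


def _check_mu(mu: ArrayLike, eps2: float, mu0: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= eps2 + MU_POLE_MARGIN - 1e-12):
        raise ValueError(
            f"mu must exceed the translation-scale pole: require mu > "
            f"{eps2 + MU_POLE_MARGIN:g} (eps2 + margin), got min {mu.min():g}")
    if np.any(mu > mu0 + 1e-9):
        raise ValueError(f"mu must not exceed mu0 = {mu0:g}, got max {mu.max():g}")
    return mu


def translation_scale(mu: ArrayLike, eps1: float, eps2: float,
                      mu_ref: float) -> ArrayLike:
    """Relative translation rate λ(μ)/λ(μ_ref) with λ ∝ (eps1-μ)/(eps2-μ).

    Equals 1 at μ = μ_ref and increases as μ decreases toward the pole
    at eps2 (both numerator and denominator negative on the valid
    domain μ > eps2).
    """
    mu = _check_mu(mu, eps2, mu_ref if mu_ref > eps2 else np.inf)
    _check_mu(mu_ref, eps2, np.inf)
    lam = (eps1 - mu) / (eps2 - mu)
    lam_ref = (eps1 - mu_ref) / (eps2 - mu_ref)
    out = lam / lam_ref
    return float(out) if np.ndim(out) == 0 else out


def effective_theta_x(mu: ArrayLike, theta_x0: float, delta: float,
                      mu0: float) -> ArrayLike:
    """Volume-corrected dissociation constant θx(μ) = exp(δ·(μ0-μ))·θx0 [AU].

    Slower growth means bigger cells, so more regulator molecules are
    needed for the same occupancy; θx(μ0) = θx0.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    out = np.exp(delta * (mu0 - mu)) * theta_x0
    return float(out) if out.ndim == 0 else out


def _scaled_alpha(gene: str, mu: ArrayLike, dp: DoseResponseParams,
                  gp: GrowthCouplingParams) -> ArrayLike:
    eps1, eps2 = gp.eps(gene)
    alpha = dp.alpha_x if gene in ("regulator", "x") else dp.alpha_y
    return translation_scale(mu, eps1, eps2, gp.mu0) * alpha


def mean_regulator(iptg: ArrayLike, dp: DoseResponseParams,
                   gp: GrowthCouplingParams, mu: ArrayLike | None = None) -> ArrayLike:
    """Mean regulator fluorescence ⟨eBFP2⟩ at inducer level ``iptg`` [AU].

    αx(μ)·(ρx + u)/(1 + u) with u = (IPTG/θi)^ni; strictly increasing
    in IPTG from αx(μ)·ρx to αx(μ).
    """
    iptg = np.asarray(iptg, dtype=float)
    if np.any(iptg < 0) or not np.all(np.isfinite(iptg)):
        raise ValueError("iptg must be finite and non-negative")
    mu = gp.mu0 if mu is None else mu
    u = (iptg / dp.theta_i) ** dp.n_i
    out = _scaled_alpha("x", mu, dp, gp) * (dp.rho_x + u) / (1.0 + u)
    return float(out) if np.ndim(out) == 0 else out


def mean_target(e_mean: ArrayLike, dp: DoseResponseParams,
                gp: GrowthCouplingParams, mu: ArrayLike | None = None) -> ArrayLike:
    """Mean target fluorescence ⟨sfGFP⟩ given regulator level ``e_mean`` [AU].

    αy(μ)·(1 + ρy·v)/(1 + v) with v = (E/θx(μ))^nx; strictly decreasing
    in E from αy(μ) to αy(μ)·ρy.
    """
    e_mean = np.asarray(e_mean, dtype=float)
    if np.any(e_mean < 0) or not np.all(np.isfinite(e_mean)):
        raise ValueError("e_mean must be finite and non-negative")
    mu = gp.mu0 if mu is None else mu
    th = effective_theta_x(mu, dp.theta_x, gp.delta, gp.mu0)
    v = (e_mean / th) ** dp.n_x
    out = _scaled_alpha("y", mu, dp, gp) * (1.0 + dp.rho_y * v) / (1.0 + v)
    return float(out) if np.ndim(out) == 0 else out


def regulator_limits(dp: DoseResponseParams, gp: GrowthCouplingParams,
                     mu: float | None = None) -> tuple[float, float]:
    """(uninduced, saturated) regulator means: (αx(μ)·ρx, αx(μ))."""
    mu = gp.mu0 if mu is None else mu
    a = float(_scaled_alpha("x", mu, dp, gp))
    return a * dp.rho_x, a


def target_limits(dp: DoseResponseParams, gp: GrowthCouplingParams,
                  mu: float | None = None) -> tuple[float, float]:
    """(fully repressed, unrepressed) target means: (αy(μ)·ρy, αy(μ))."""
    mu = gp.mu0 if mu is None else mu
    a = float(_scaled_alpha("y", mu, dp, gp))
    return a * dp.rho_y, a


def evaluate_condition(c: Condition, dp: DoseResponseParams,
                       gp: GrowthCouplingParams) -> MeanState:
    """Compose growth, regulator and target means for one condition.

    μ = μ(TC); E = ⟨eBFP2⟩(IPTG, μ); G = ⟨sfGFP⟩(E, μ); SR = mean·μ.
    """
    mu = float(growth_rate(c.tc, gp))
    e = float(mean_regulator(c.iptg, dp, gp, mu))
    g = float(mean_target(e, dp, gp, mu))
    return MeanState(mu=mu, e_mean=e, g_mean=g, sr_e=e * mu, sr_g=g * mu)


def dose_response_table(conditions: Iterable[Condition], dp: DoseResponseParams,
                        gp: GrowthCouplingParams,
                        path: Union[str, Path, None] = None) -> pd.DataFrame:
    """Evaluate a condition grid into a tidy table.

    Columns: iptg_uM, tc_ng_mL, mu, e_mean, g_mean, sr_e, sr_g.
    Written as CSV when ``path`` is given.
    """
    rows = []
    for c in conditions:
        s = evaluate_condition(c, dp, gp)
        rows.append(dict(iptg_uM=c.iptg, tc_ng_mL=c.tc, mu=s.mu, e_mean=s.e_mean,
                         g_mean=s.g_mean, sr_e=s.sr_e, sr_g=s.sr_g))
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def relative_sr_curve(gene: Literal["regulator", "target"], iptg: float,
                      mu_grid: Sequence[float], dp: DoseResponseParams,
                      gp: GrowthCouplingParams) -> np.ndarray:
    """Synthesis rate relative to the TC=0 state, SR(μ)/SR(μ0), on ``mu_grid``.

    For the regulator this reduces to translation_scale(μ)·(μ/μ0) and is
    independent of IPTG (transcriptional control decouples from growth);
    for the target the IPTG level matters because the regulator amount
    and θx(μ) both move with μ.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    if gene == "regulator":
        return translation_scale(mu_grid, gp.eps1_x, gp.eps2_x, gp.mu0) * mu_grid / gp.mu0
    if gene == "target":
        e = mean_regulator(iptg, dp, gp, mu_grid)
        g = mean_target(e, dp, gp, mu_grid)
        e0 = mean_regulator(iptg, dp, gp, gp.mu0)
        g0 = mean_target(e0, dp, gp, gp.mu0)
        return g * mu_grid / (g0 * gp.mu0)
    raise ValueError(f"unknown gene {gene!r}")


class BoundaryExtremumError(ValueError):
    """Raised when the sought extremum sits on the search-interval boundary."""


def locate_extremum(f: Callable[[float], float], interval: tuple[float, float],
                    mode: Literal["min", "max"] = "min", n_grid: int = 2000,
                    tol: float = 0.005) -> float:
    """Argument of the interior extremum of ``f`` on ``interval`` [h⁻¹].

    Dense uniform grid scan followed by bounded golden-section/Brent
    refinement; accurate to better than ``tol`` for smooth unimodal
    curves.  A grid extremum on the boundary raises
    :class:`BoundaryExtremumError` (no interior extremum).
    """
    lo, hi = interval
    if not lo < hi:
        raise ValueError("interval must satisfy lo < hi")
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([f(m) for m in grid])
    if not np.all(np.isfinite(vals)):
        raise ValueError("curve evaluator returned non-finite values on the interval")
    idx = int(np.argmin(vals) if mode == "min" else np.argmax(vals))
    if idx in (0, n_grid - 1):
        raise BoundaryExtremumError(
            f"{mode} of curve on [{lo:g}, {hi:g}] lies on the boundary; "
            "no interior extremum")
    sign = 1.0 if mode == "min" else -1.0
    res = minimize_scalar(lambda m: sign * f(m), bounds=(grid[idx - 1], grid[idx + 1]),
                          method="bounded", options={"xatol": tol / 10})
    return float(res.x)


_SCALABLE = {f.name for f in fields(DoseResponseParams)} | \
            {f.name for f in fields(NoiseParams)} | {"theta_c", "delta"}


def sensitivity_scan(param: str, iptg_grid: Sequence[float],
                     dp: DoseResponseParams, gp: GrowthCouplingParams,
                     npar: NoiseParams | None = None, tc: float = 0.0,
                     factor: float = 2.0) -> pd.DataFrame:
    """Two-fold one-at-a-time sensitivity of the IPTG dose responses.

    Re-evaluates mean (and, when ``npar`` is given, total-noise) curves
    with the named parameter multiplied by ``factor`` and by
    ``1/factor``, all other parameters fixed.  Returns a long table with
    columns perturbation ∈ {x2, x0.5, base}, iptg_uM, e_mean, g_mean
    (+ cv2_e, cv2_g with ``npar``).
    """
    if param not in _SCALABLE:
        raise KeyError(f"unknown or non-scalable parameter {param!r}")
    iptg_grid = np.asarray(iptg_grid, dtype=float)

    def variant(scale: float):
        d, g, n = dp, gp, npar
        for obj_name, obj in (("dp", d), ("gp", g), ("npar", n)):
            if obj is not None and param in {f.name for f in fields(obj)}:
                new = replace(obj, **{param: getattr(obj, param) * scale})
                if obj_name == "dp":
                    d = new
                elif obj_name == "gp":
                    g = new
                else:
                    n = new
        return d, g, n

    from . import noise as _noise  # local import to avoid a cycle

    rows = []
    for label, scale in (("base", 1.0), ("x2", factor), ("x0.5", 1.0 / factor)):
        d, g, n = variant(scale)
        mu = float(growth_rate(tc, g))
        for iptg in iptg_grid:
            e = float(mean_regulator(iptg, d, g, mu))
            gm = float(mean_target(e, d, g, mu))
            row = dict(perturbation=label, iptg_uM=float(iptg), e_mean=e, g_mean=gm)
            if n is not None:
                c = Condition(iptg=float(iptg), tc=tc)
                row["cv2_e"] = _noise.cv2_regulator(c, d, g, n).total
                row["cv2_g"] = _noise.cv2_target(c, d, g, n).total
            rows.append(row)
    return pd.DataFrame(rows)
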