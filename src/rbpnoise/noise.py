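"""Analytic noise of the cascade: CV² decomposition and Gamma predictions.

The squared coefficient of variation of each gene splits into three
additive components:

* extrinsic — shared-machinery variability, a constant CV² plateau;
* intrinsic — finite-copy-number noise, (Fano factor)/mean;
* regulation — noise propagated from upstream, ∝ (transfer-function
  slope)² × upstream variance / mean², with a 1/2 prefactor from
  time-averaging of the colored upstream fluctuations.

For the regulator the upstream source is LacI activity (IPTG-equivalent
variance eta2_lac); for the target it is the regulator itself, with
gamma_y converting fluorescence variance to the molecular variance that
actually propagates.  Growth rate rescales the constants: Fano factor
and extrinsic plateaus follow the translation rate, the LacI term
follows (μ/μ0)².

Single-cell expression is Gamma distributed with shape 1/CV² and scale
mean·CV² (an effective Fano factor).
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .deterministic import (effective_theta_x, evaluate_condition, growth_rate,
                            mean_regulator, translation_scale)
from .params import (Condition, DoseResponseParams, GammaParams,
                     GrowthCouplingParams, NoiseDecomposition, NoiseParams)

__all__ = [
    "noise_params_at_growth",
    "d_regulator_d_iptg",
    "d_target_d_regulator",
    "cv2_regulator",
    "cv2_target",
    "regulation_noise_peak",
    "gamma_from_moments",
    "gamma_pdf",
    "predict_distribution",
    "decomposition_table",
]


def noise_params_at_growth(np0: NoiseParams, mu: float,
                           gp: GrowthCouplingParams) -> NoiseParams:
    """Noise constants rescaled from μ0 to growth rate ``mu``.

    beta_x and eta2_x follow the regulator translation scale, eta2_y the
    target one, eta2_lac scales as (μ/μ0)²; beta_y (abundant constitutive
    mRNA) and gamma_y are growth-independent.
    """
    sx = float(translation_scale(mu, gp.eps1_x, gp.eps2_x, gp.mu0))
    sy = float(translation_scale(mu, gp.eps1_y, gp.eps2_y, gp.mu0))
    return replace(np0,
                   beta_x=np0.beta_x * sx,
                   eta2_x=np0.eta2_x * sx,
                   eta2_y=np0.eta2_y * sy,
                   eta2_lac=np0.eta2_lac * (mu / gp.mu0) ** 2)


def d_regulator_d_iptg(iptg: float, dp: DoseResponseParams,
                       gp: GrowthCouplingParams, mu: float | None = None) -> float:
    """Closed-form slope d⟨eBFP2⟩/dIPTG of the regulator dose response [AU/μM]."""
    if iptg < 0:
        raise ValueError("iptg must be non-negative")
    mu = gp.mu0 if mu is None else mu
    alpha = float(translation_scale(mu, gp.eps1_x, gp.eps2_x, gp.mu0)) * dp.alpha_x
    r = iptg / dp.theta_i
    u = r ** dp.n_i
    lead = r ** (dp.n_i - 1.0) if iptg > 0 else (1.0 if dp.n_i == 1.0 else 0.0)
    return alpha * (1.0 - dp.rho_x) * dp.n_i * lead / (dp.theta_i * (1.0 + u) ** 2)


def d_target_d_regulator(e_mean: float, dp: DoseResponseParams,
                         gp: GrowthCouplingParams, mu: float | None = None) -> float:
    """Closed-form slope d⟨sfGFP⟩/d⟨eBFP2⟩ of the repression transfer function.

    Negative (repression); magnitude αy(μ)(1-ρy)·nx·(E/θx)^{nx-1} /
    (θx·(1+(E/θx)^nx)²) with growth-corrected αy and θx.
    """
    if e_mean < 0:
        raise ValueError("e_mean must be non-negative")
    mu = gp.mu0 if mu is None else mu
    alpha = float(translation_scale(mu, gp.eps1_y, gp.eps2_y, gp.mu0)) * dp.alpha_y
    th = float(effective_theta_x(mu, dp.theta_x, gp.delta, gp.mu0))
    r = e_mean / th
    v = r ** dp.n_x
    lead = r ** (dp.n_x - 1.0) if e_mean > 0 else (1.0 if dp.n_x == 1.0 else 0.0)
    return -alpha * (1.0 - dp.rho_y) * dp.n_x * lead / (th * (1.0 + v) ** 2)


def cv2_regulator(c: Condition, dp: DoseResponseParams, gp: GrowthCouplingParams,
                  npar: NoiseParams) -> NoiseDecomposition:
    """Noise decomposition of the regulator at condition ``c``.

    extrinsic = eta2_x(μ); intrinsic = beta_x(μ)/E;
    regulation = ½·(dE/dIPTG)²·eta2_lac(μ)/E².
    """
    mu = float(growth_rate(c.tc, gp))
    nmu = noise_params_at_growth(npar, mu, gp)
    e = float(mean_regulator(c.iptg, dp, gp, mu))
    if e <= 0 or e * e == 0.0:
        raise ValueError("regulator mean must be positive (and not underflow)")
    slope = d_regulator_d_iptg(c.iptg, dp, gp, mu)
    return NoiseDecomposition(
        extrinsic=nmu.eta2_x,
        intrinsic=nmu.beta_x / e,
        regulation=0.5 * slope**2 * nmu.eta2_lac / e**2,
    )


def cv2_target(c: Condition, dp: DoseResponseParams, gp: GrowthCouplingParams,
               npar: NoiseParams) -> NoiseDecomposition:
    """Noise decomposition of the target at condition ``c``.

    extrinsic = eta2_y(μ); intrinsic = beta_y/G;
    regulation = ½·(dG/dE)²·gamma_y·E²/G²·CV²_E with CV²_E the full
    regulator total (all three components).
    """
    mu = float(growth_rate(c.tc, gp))
    nmu = noise_params_at_growth(npar, mu, gp)
    st = evaluate_condition(c, dp, gp)
    if st.e_mean <= 0 or st.g_mean <= 0:
        raise ValueError("means must be positive")
    cv2_e = cv2_regulator(c, dp, gp, npar).total
    slope = d_target_d_regulator(st.e_mean, dp, gp, mu)
    return NoiseDecomposition(
        extrinsic=nmu.eta2_y,
        intrinsic=nmu.beta_y / st.g_mean,
        regulation=0.5 * slope**2 * nmu.gamma_y * st.e_mean**2 / st.g_mean**2 * cv2_e,
    )


def regulation_noise_peak(gene: Literal["regulator", "target"],
                          iptg_grid: Sequence[float], dp: DoseResponseParams,
                          gp: GrowthCouplingParams, npar: NoiseParams,
                          tc: float = 0.0) -> tuple[float, float]:
    """(argmax IPTG, max value) of the regulation-noise component on the grid.

    The component follows a peak-like curve in IPTG: zero where the
    transfer-function slope vanishes, maximal in the transition region.
    """
    iptg_grid = np.asarray(iptg_grid, dtype=float)
    if iptg_grid.size == 0:
        raise ValueError("empty IPTG grid")
    fn = cv2_regulator if gene == "regulator" else cv2_target
    vals = np.array([fn(Condition(iptg=float(i), tc=tc), dp, gp, npar).regulation
                     for i in iptg_grid])
    k = int(np.argmax(vals))
    return float(iptg_grid[k]), float(vals[k])


def gamma_from_moments(mean: float, cv2: float) -> GammaParams:
    """Mesoscopic Gamma parameterization: shape = 1/CV², scale = mean·CV²."""
    if mean <= 0 or cv2 <= 0:
        raise ValueError("mean and cv2 must be positive")
    return GammaParams(shape=1.0 / cv2, scale=mean * cv2)


def gamma_pdf(x, g: GammaParams):
    """Gamma density at ``x`` [AU⁻¹]; x^{a-1} e^{-x/b} / (Γ(a) b^a)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    out = stats.gamma.pdf(x, a=g.shape, scale=g.scale)
    return float(out) if out.ndim == 0 else out


def predict_distribution(c: Condition, dp: DoseResponseParams,
                         gp: GrowthCouplingParams, npar: NoiseParams,
                         channel: Literal["regulator", "target"]) -> GammaParams:
    """Predicted single-cell fluorescence distribution for one channel.

    Composes the deterministic mean with the analytic CV² into the
    Gamma law; for the regulator the scale (effective Fano factor)
    tracks the translation rate through beta_x/eta2_x, while the target
    scale is nearly independent of it (translational control).
    """
    st = evaluate_condition(c, dp, gp)
    if channel == "regulator":
        return gamma_from_moments(st.e_mean, cv2_regulator(c, dp, gp, npar).total)
    if channel == "target":
        return gamma_from_moments(st.g_mean, cv2_target(c, dp, gp, npar).total)
    raise ValueError(f"unknown channel {channel!r}")


def decomposition_table(conditions: Iterable[Condition], dp: DoseResponseParams,
                        gp: GrowthCouplingParams, npar: NoiseParams,
                        path: Union[str, Path, None] = None) -> pd.DataFrame:
    """Tidy table of both channels' noise decompositions over a condition grid.

    Columns: iptg_uM, tc_ng_mL, channel, extrinsic, intrinsic,
    regulation, total, gamma_shape, gamma_scale.
    """
    rows = []
    for c in conditions:
        for channel, fn in (("regulator", cv2_regulator), ("target", cv2_target)):
            d = fn(c, dp, gp, npar)
            g = predict_distribution(c, dp, gp, npar, channel)
            rows.append(dict(iptg_uM=c.iptg, tc_ng_mL=c.tc, channel=channel,
                             extrinsic=d.extrinsic, intrinsic=d.intrinsic,
                             regulation=d.regulation, total=d.total,
                             gamma_shape=g.shape, gamma_scale=g.scale))
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
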