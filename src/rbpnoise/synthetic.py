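"""Synthetic flow-cytometry events, growth curves, and volume proxies.

Emulates the statistical structure of the characterization data so the
full inference chain is testable without any measurement: per-condition
single-cell fluorescence is Gamma distributed with the model's mean and
CV², on top of a Gaussian autofluorescence background, with a small
fraction of uniform outliers; growth curves are exponential with the
Michaelis-Menten TC dependence, multiplicative noise, and a stationary
ceiling; the forward-scatter proxy has median fsc³ following the
exponential volume trend in growth rate.

Canonical on-disk format: delimited text with header
``replicate,iptg_uM,tc_ng_mL,ebfp2_au,sfgfp_au,fsc_au`` (events) and
``replicate,iptg_uM,tc_ng_mL,time_h,od600`` (growth curves).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .deterministic import growth_rate
from .noise import predict_distribution
from .params import (Condition, DoseResponseParams, GrowthCouplingParams,
                     NoiseParams)

__all__ = [
    "EVENT_COLUMNS",
    "GROWTH_COLUMNS",
    "sample_events",
    "simulate_growth_curves",
    "simulate_volume_proxy",
    "write_events",
    "read_events",
    "read_events_xlsx",
]

EVENT_COLUMNS = ("replicate", "iptg_uM", "tc_ng_mL", "ebfp2_au", "sfgfp_au", "fsc_au")
GROWTH_COLUMNS = ("replicate", "iptg_uM", "tc_ng_mL", "time_h", "od600")

#: Default Gaussian autofluorescence background per channel [AU].
DEFAULT_AUTOFLUO_MEAN = 100.0
DEFAULT_AUTOFLUO_SD = 30.0


def sample_events(c: Condition, dp: DoseResponseParams, gp: GrowthCouplingParams,
                  npar: NoiseParams, n: int, seed: int,
                  autofluo_mean: float = DEFAULT_AUTOFLUO_MEAN,
                  autofluo_sd: float = DEFAULT_AUTOFLUO_SD,
                  outlier_frac: float = 0.0, replicate: int = 1,
                  correlated: bool = False, with_fsc: bool = True) -> pd.DataFrame:
    """Draw ``n`` synthetic cytometry events for one condition.

    Each channel is Gamma distributed per the model prediction, plus
    Gaussian autofluorescence; a fraction ``outlier_frac`` of events is
    replaced by uniform outliers on [0, 10·P99] of the clean channel.
    By default channels are independent (the analytic model constrains
    only the marginals); ``correlated=True`` instead maps each cell's
    regulator quantile through the repression transfer function, giving
    the negative association a joint readout would show.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= outlier_frac <= 0.05:
        raise ValueError("outlier_frac must be in [0, 0.05]")
    if autofluo_sd < 0:
        raise ValueError("autofluo_sd must be >= 0")
    rng = np.random.default_rng(seed)

    ge = predict_distribution(c, dp, gp, npar, "regulator")
    gg = predict_distribution(c, dp, gp, npar, "target")
    ebfp2 = rng.gamma(ge.shape, ge.scale, size=n)
    if correlated:
        # map the regulator quantile through the (decreasing) transfer
        # function: high-regulator cells sit at low target quantiles
        from scipy import stats
        q = stats.gamma.cdf(ebfp2, a=ge.shape, scale=ge.scale)
        sfgfp = stats.gamma.ppf(1.0 - q, a=gg.shape, scale=gg.scale)
    else:
        sfgfp = rng.gamma(gg.shape, gg.scale, size=n)

    for vals in (ebfp2, sfgfp):
        k = int(round(outlier_frac * n))
        if k:
            idx = rng.choice(n, size=k, replace=False)
            vals[idx] = rng.uniform(0.0, 10.0 * np.quantile(vals, 0.99), size=k)

    ebfp2 = ebfp2 + rng.normal(autofluo_mean, autofluo_sd, size=n)
    sfgfp = sfgfp + rng.normal(autofluo_mean, autofluo_sd, size=n)

    df = pd.DataFrame({
        "replicate": replicate,
        "iptg_uM": c.iptg,
        "tc_ng_mL": c.tc,
        "ebfp2_au": ebfp2,
        "sfgfp_au": sfgfp,
    })
    if with_fsc:
        mu = float(growth_rate(c.tc, gp))
        df["fsc_au"] = simulate_volume_proxy(
            mu, gp, n, seed=int(rng.integers(2**31)))
    else:
        df["fsc_au"] = np.nan
    return df


def simulate_growth_curves(c: Condition, gp: GrowthCouplingParams,
                           times: Sequence[float], od0: float = 0.01,
                           noise_sd: float = 0.02, seed: int = 0,
                           od_max: float = 1.0, replicate: int = 1) -> pd.DataFrame:
    """Exponential-phase absorbance curve for one condition.

    OD(t) = od0·exp(μ(TC)·t)·(1+ε) with multiplicative Gaussian noise of
    sd ``noise_sd``, capped at the stationary ceiling ``od_max``; the
    log-slope during the exponential window equals μ(TC) by
    construction.
    """
    if od0 <= 0:
        raise ValueError("od0 must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    mu = float(growth_rate(c.tc, gp))
    od = np.minimum(od0 * np.exp(mu * times), od_max)
    od = od * (1.0 + rng.normal(0.0, noise_sd, size=times.size))
    od = np.maximum(od, 1e-6)
    return pd.DataFrame({"replicate": replicate, "iptg_uM": c.iptg,
                         "tc_ng_mL": c.tc, "time_h": times, "od600": od})


def simulate_volume_proxy(mu: float, gp: GrowthCouplingParams, n: int, seed: int,
                          baseline_fsc3: float = 1.0,
                          lognorm_sigma: float = 0.2) -> np.ndarray:
    """Forward-scatter values whose cubed median follows the volume trend.

    median(fsc³) = baseline·exp(delta·(mu0-μ)): slower-growing cells
    are bigger.  Event-level scatter is lognormal (median-preserving).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mu <= 0 or mu > gp.mu0 + 1e-9:
        raise ValueError(f"mu must be in (0, mu0={gp.mu0:g}]")
    rng = np.random.default_rng(seed)
    med_fsc3 = baseline_fsc3 * np.exp(gp.delta * (gp.mu0 - mu))
    return med_fsc3 ** (1.0 / 3.0) * rng.lognormal(0.0, lognorm_sigma, size=n)


def write_events(path: Union[str, Path], events: pd.DataFrame) -> None:
    """Write an event table in the canonical delimited format."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    events.loc[:, EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path: Union[str, Path]) -> pd.DataFrame:
    """Read a canonical event table, reporting malformed rows by line number.

    Unknown extra columns are warned about and dropped, not fatal.
    """
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in EVENT_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
        df = df.drop(columns=extra)
    numeric = [c for c in EVENT_COLUMNS if c != "replicate"]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line and 1-based numbering
            lines = [int(i) + 2 for i in df.index[bad][:5]]
            raise ValueError(f"{path}: non-numeric value(s) in column "
                             f"{col!r} at line(s) {lines}")
        df[col] = coerced
    return df


def read_events_xlsx(path: Union[str, Path]) -> pd.DataFrame:
    """Best-effort reader for the deposited-spreadsheet layout (synthetic-friendly).

    Accepts a workbook whose sheets each hold one condition block with
    two fluorescence columns (regulator then target); condition labels
    are parsed from sheet names of the form ``IPTG<x>_TC<y>`` or read
    from ``iptg_uM``/``tc_ng_mL`` columns when present.  Returns the
    canonical event table.
    """
    import re
    book = pd.read_excel(path, sheet_name=None)
    frames = []
    for name, sheet in book.items():
        sheet = sheet.dropna(how="all")
        if {"iptg_uM", "tc_ng_mL"}.issubset(sheet.columns):
            iptg = float(sheet["iptg_uM"].iloc[0])
            tc = float(sheet["tc_ng_mL"].iloc[0])
        else:
            m = re.match(r"IPTG([\d.]+)_TC([\d.]+)", str(name))
            if not m:
                warnings.warn(f"sheet {name!r}: cannot parse condition; skipped",
                              stacklevel=2)
                continue
            iptg, tc = float(m.group(1)), float(m.group(2))
        fluo_cols = [c for c in sheet.columns
                     if sheet[c].dtype.kind in "fi"][:2]
        if len(fluo_cols) < 2:
            warnings.warn(f"sheet {name!r}: fewer than two numeric columns; skipped",
                          stacklevel=2)
            continue
        frames.append(pd.DataFrame({
            "replicate": 1, "iptg_uM": iptg, "tc_ng_mL": tc,
            "ebfp2_au": sheet[fluo_cols[0]].to_numpy(dtype=float),
            "sfgfp_au": sheet[fluo_cols[1]].to_numpy(dtype=float),
            "fsc_au": np.nan,
        }))
    if not frames:
        raise ValueError(f"{path}: no readable condition sheets")
    return pd.concat(frames, ignore_index=True)
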