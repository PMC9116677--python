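"""Parameter containers and flat key-value configuration I/O.

The model describes a two-gene cascade in *E. coli*: an IPTG-inducible
regulator (eBFP2-MS2CP, a fluorescent RNA-binding translation factor)
that represses translation of a constitutively transcribed target
(sfGFP) by binding an RNA motif on the target mRNA.  Sublethal
tetracycline (TC) modulates the growth rate and, through it, the
translation machinery.

Parameters are grouped into three frozen dataclasses mirroring how they
are estimated: dose-response (Hill-Langmuir) constants, growth-coupling
constants, and noise constants.  A bundled YAML file carries the fitted
values for the characterized circuit; :func:`load_params` reads any
flat key-value file with the same keys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "Condition",
    "DoseResponseParams",
    "GrowthCouplingParams",
    "NoiseParams",
    "MeanState",
    "NoiseDecomposition",
    "GammaParams",
    "SimConfig",
    "load_params",
    "save_params",
    "default_params",
    "IPTG_GRADIENT",
    "TC_GRADIENT",
]

#: Inducer gradients used to characterize the circuit (μM and ng/mL).
IPTG_GRADIENT = (0.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0)
TC_GRADIENT = (0.0, 10.0, 100.0, 200.0, 300.0, 400.0, 500.0, 700.0, 1000.0)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class Condition:
    """One induction condition: IPTG in μM, TC in ng/mL."""

    iptg: float = 0.0
    tc: float = 0.0

    def __post_init__(self) -> None:
        _require(math.isfinite(self.iptg) and self.iptg >= 0.0,
                 f"iptg must be finite and >= 0, got {self.iptg}")
        _require(math.isfinite(self.tc) and self.tc >= 0.0,
                 f"tc must be finite and >= 0, got {self.tc}")


@dataclass(frozen=True)
class DoseResponseParams:
    """Hill-Langmuir constants of the two transfer functions.

    ``alpha_x`` [AU] maximal regulator expression; ``rho_x`` (0,1)
    transcriptional repression fold by LacI; ``theta_i`` [μM] LacI-IPTG
    effective dissociation constant; ``n_i`` cooperativity;
    ``alpha_y`` [AU] maximal target expression; ``rho_y`` (0,1)
    translational repression fold; ``theta_x`` [AU] regulator-motif
    effective dissociation constant; ``n_x`` cooperativity.
    """

    alpha_x: float = 1890.0
    rho_x: float = 0.225
    theta_i: float = 116.0
    n_i: float = 2.38
    alpha_y: float = 29000.0
    rho_y: float = 0.016
    theta_x: float = 610.0
    n_x: float = 5.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _require(math.isfinite(v) and v > 0, f"{f.name} must be positive, got {v}")
        _require(self.rho_x < 1.0, f"rho_x must be < 1, got {self.rho_x}")
        _require(self.rho_y < 1.0, f"rho_y must be < 1, got {self.rho_y}")


@dataclass(frozen=True)
class GrowthCouplingParams:
    """Growth and growth-coupling constants.

    ``mu0`` [h^-1] maximal growth rate; ``theta_c`` [ng/mL] TC
    half-inhibition; ``eps1_*``/``eps2_*`` [h^-1] translation-scaling
    constants of each gene (translation rate ∝ (eps1-μ)/(eps2-μ));
    ``delta`` [h] cell-volume correction exponent for ``theta_x``.
    """

    mu0: float = 1.2
    theta_c: float = 526.0
    eps1_x: float = 0.196
    eps2_x: float = 0.299
    eps1_y: float = 0.246
    eps2_y: float = 0.349
    delta: float = 0.85

    def __post_init__(self) -> None:
        _require(self.mu0 > 0, "mu0 must be positive")
        _require(self.theta_c > 0, "theta_c must be positive")
        for g in ("x", "y"):
            e1 = getattr(self, f"eps1_{g}")
            e2 = getattr(self, f"eps2_{g}")
            _require(e1 < e2 < self.mu0,
                     f"need eps1_{g} < eps2_{g} < mu0, got {e1}, {e2}, {self.mu0}")

    def eps(self, gene: str) -> tuple[float, float]:
        """(eps1, eps2) for ``gene`` in {'regulator'|'x', 'target'|'y'}."""
        g = {"regulator": "x", "target": "y", "x": "x", "y": "y"}[gene]
        return getattr(self, f"eps1_{g}"), getattr(self, f"eps2_{g}")


@dataclass(frozen=True)
class NoiseParams:
    """Constants of the three-component noise decomposition.

    ``eta2_x``/``eta2_y`` extrinsic-noise CV² plateaus (dimensionless);
    ``beta_x``/``beta_y`` [AU] intrinsic-noise Fano factors;
    ``eta2_lac`` [μM²] LacI expression-noise constant (IPTG-equivalent
    variance); ``gamma_y`` fluorescence-to-molecule conversion constant.
    """

    eta2_x: float = 0.246
    beta_x: float = 45.6
    eta2_lac: float = 6470.0
    eta2_y: float = 0.127
    beta_y: float = 61.9
    gamma_y: float = 0.0233

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _require(math.isfinite(v) and v > 0, f"{f.name} must be positive, got {v}")


@dataclass(frozen=True)
class MeanState:
    """Deterministic state at one condition.

    ``mu`` [h^-1]; mean fluorescences ``e_mean`` (regulator, eBFP2) and
    ``g_mean`` (target, sfGFP) [AU]; synthesis rates ``sr_e``, ``sr_g``
    [AU·h^-1] with SR = mean × μ (stable proteins).
    """

    mu: float
    e_mean: float
    g_mean: float
    sr_e: float
    sr_g: float


@dataclass(frozen=True)
class NoiseDecomposition:
    """CV² split into extrinsic + intrinsic + regulation components."""

    extrinsic: float
    intrinsic: float
    regulation: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _require(math.isfinite(v) and v >= 0.0, f"{f.name} must be >= 0, got {v}")

    @property
    def total(self) -> float:
        return self.extrinsic + self.intrinsic + self.regulation


@dataclass(frozen=True)
class GammaParams:
    """Mesoscopic Gamma parameterization: shape a = 1/CV², scale b = mean·CV² [AU]."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        _require(self.shape > 0, "shape must be positive")
        _require(self.scale > 0, "scale must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale**2

    @property
    def cv2(self) -> float:
        return 1.0 / self.shape


@dataclass(frozen=True)
class SimConfig:
    """Langevin integration settings.

    ``horizon`` [h] total simulated time; ``update_interval`` [h] the
    interval over which fluctuation values are held constant;
    ``tau_ext`` [h] correlation time of colored (extrinsic/regulation)
    noise, ``None`` meaning 1/μ of the simulated condition;
    ``burn_in`` [h] discarded initial time.
    """

    horizon: float = 50.0
    update_interval: float = 0.01
    n_trajectories: int = 200
    seed: int = 0
    burn_in: float = 10.0
    tau_ext: float | None = None

    def __post_init__(self) -> None:
        _require(self.horizon > 0 and self.update_interval > 0, "times must be positive")
        _require(self.update_interval < self.horizon, "update_interval must be < horizon")
        _require(0 <= self.burn_in < self.horizon, "burn_in must be in [0, horizon)")
        _require(self.n_trajectories >= 1, "need at least one trajectory")
        if self.tau_ext is not None:
            _require(self.update_interval < self.tau_ext < self.horizon,
                     "need update_interval < tau_ext < horizon")


_GROUPS = (DoseResponseParams, GrowthCouplingParams, NoiseParams)


def _group_keys() -> dict[str, type]:
    out: dict[str, type] = {}
    for cls in _GROUPS:
        for f in fields(cls):
            out[f.name] = cls
    return out


def load_params(path: Union[str, Path]) -> tuple[DoseResponseParams, GrowthCouplingParams, NoiseParams]:
    """Read a flat key-value (YAML) parameter file.

    Keys are exactly the dataclass field names; unknown keys raise.
    Returns ``(dose_response, growth_coupling, noise)``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} is not a flat key-value mapping")
    known = _group_keys()
    unknown = sorted(set(raw) - set(known))
    if unknown:
        raise ValueError(f"unknown parameter keys in {path}: {unknown}")
    per: dict[type, dict[str, float]] = {cls: {} for cls in _GROUPS}
    for k, v in raw.items():
        per[known[k]][k] = float(v)
    return (DoseResponseParams(**per[DoseResponseParams]),
            GrowthCouplingParams(**per[GrowthCouplingParams]),
            NoiseParams(**per[NoiseParams]))


def save_params(path: Union[str, Path],
                dp: DoseResponseParams,
                gp: GrowthCouplingParams,
                npar: NoiseParams | None = None) -> None:
    """Write parameters as a flat key-value YAML file reusable by :func:`load_params`."""
    lines = ["# rbpnoise parameter set (flat key-value; units in field docs)"]
    groups = [dp, gp] + ([npar] if npar is not None else [])
    for obj in groups:
        lines.append(f"# {type(obj).__name__}")
        for f in fields(obj):
            lines.append(f"{f.name}: {getattr(obj, f.name)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def default_params() -> tuple[DoseResponseParams, GrowthCouplingParams, NoiseParams]:
    """The bundled fitted parameter set of the characterized MS2CP circuit."""
    with resources.as_file(resources.files("rbpnoise.data") / "default_params.yaml") as p:
        return load_params(p)
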