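"""Physical parameters, unit conventions, and the BOLD signal equations.

All quantities are SI: times in seconds, field in Tesla, susceptibilities
dimensionless (SI volume susceptibility), angles in radians.  Field offsets
are carried internally as *relative* offsets ``dBz/B0``; phase accumulated
over an echo time is ``gamma * b0 * (dBz/B0) * te``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "SimulationParams",
    "OscillationSpec",
    "blood_tissue_susceptibility",
    "relaxation_times",
    "steady_state_prefactor",
    "steady_state_signal",
    "oscillate",
]

#: volume susceptibility of fully deoxygenated blood relative to water (SI)
DELTA_CHI_DEOXY = 4.0 * math.pi * 0.27e-6


@dataclass(frozen=True)
class SimulationParams:
    """Sequence and physiology parameters of a simulated GRE-BOLD run.

    Defaults match a 3 T resting-state protocol: TR 2.2 s, TE 27 ms, 90°
    flip, 4 mm voxels, 30 min runs.  Oxygenation fractions ``y_a``/``y_v``/
    ``y_tissue`` are the arterial, venous and tissue reference values.
    """

    delta_chi: float = DELTA_CHI_DEOXY
    hct: float = 0.4
    b0: float = 3.0
    te: float = 0.027
    tr: float = 2.2
    alpha: float = math.pi / 2
    y_a: float = 0.98
    y_v: float = 0.6
    y_tissue: float = 0.85
    t1_blood: float = 1.649
    t1_tissue: float = 1.465
    gamma: float = 2.0 * math.pi * 42.58e6
    n_frames: int = 818  # floor(30 min / 2.2 s)
    #: coefficients (A, B, C) of the blood relaxometry law
    #: 1/T2 = A + B*(1-Y) + C*(1-Y)^2, in 1/s, at 3 T
    t2_blood_coeffs: tuple[float, float, float] = (4.0, 35.0, 300.0)
    t2_tissue: float = 0.066
    #: steady-state equation form: "as_printed" keeps exp(-TE/T2) inside the
    #: denominator; "spgr" uses the textbook spoiled-GRE form with a
    #: multiplicative exp(-TE/T2) decay.
    eq4_form: Literal["as_printed", "spgr"] = "as_printed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.hct <= 1.0:
            raise ValueError(f"hct must be in [0, 1], got {self.hct}")
        for name in ("y_a", "y_v", "y_tissue"):
            y = getattr(self, name)
            if not 0.0 <= y <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {y}")
        if not self.te < self.tr:
            raise ValueError(f"te ({self.te}) must be smaller than tr ({self.tr})")
        for name in ("te", "tr", "t1_blood", "t1_tissue", "t2_tissue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def omega0(self) -> float:
        """Larmor angular frequency ``gamma * b0`` in rad/s."""
        return self.gamma * self.b0

    def replace(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)

    @classmethod
    def from_config(cls, path: str | Path) -> "SimulationParams":
        """Load parameters from a YAML/JSON file.

        Recognized keys mirror the parameter table by name: ``delta_chi``,
        ``hct``, ``b0``, ``te``, ``tr``, ``alpha_deg``, ``y_a``, ``y_v``,
        ``y_tissue``, ``t1_blood_ms``, ``t1_tissue_ms`` plus any dataclass
        field name directly (SI units).
        """
        path = Path(path)
        text = path.read_text()
        cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(cfg or {})

    @classmethod
    def from_dict(cls, cfg: dict) -> "SimulationParams":
        cfg = dict(cfg)
        kwargs: dict = {}
        if "alpha_deg" in cfg:
            kwargs["alpha"] = math.radians(cfg.pop("alpha_deg"))
        if "t1_blood_ms" in cfg:
            kwargs["t1_blood"] = cfg.pop("t1_blood_ms") / 1000.0
        if "t1_tissue_ms" in cfg:
            kwargs["t1_tissue"] = cfg.pop("t1_tissue_ms") / 1000.0
        if "t2_blood_coeffs" in cfg:
            kwargs["t2_blood_coeffs"] = tuple(cfg.pop("t2_blood_coeffs"))
        valid = set(cls.__dataclass_fields__)
        unknown = set(cfg) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(cfg)
        return cls(**kwargs)


@dataclass(frozen=True)
class OscillationSpec:
    """A sinusoidal resting-state driver for fBV (arteries) or Y (veins).

    ``peak_to_peak_fraction`` is the total swing as a fraction of the
    baseline ("±10 % peak-to-peak" means 0.10, i.e. amplitude 5 %).
    """

    target: Literal["arterial_fbv", "venous_y"]
    baseline: float
    peak_to_peak_fraction: float = 0.10
    frequency: float = 0.1
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_to_peak_fraction < 0:
            raise ValueError("peak_to_peak_fraction must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        hi = self.baseline * (1 + self.peak_to_peak_fraction / 2)
        lo = self.baseline * (1 - self.peak_to_peak_fraction / 2)
        # oxygenation is a fraction; fBV baselines may be relative scales
        # (whole-volume scenes rescale each vessel's radius by sqrt of this)
        if lo < 0.0 or (self.target == "venous_y" and hi > 1.0):
            raise ValueError(
                f"oscillation leaves the physical range: [{lo:.4g}, {hi:.4g}]"
            )

    @property
    def amplitude(self) -> float:
        return self.baseline * self.peak_to_peak_fraction / 2.0


def oscillate(spec: OscillationSpec, t) -> np.ndarray | float:
    """Instantaneous value of the oscillating quantity at time ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    val = spec.baseline * (
        1.0
        + (spec.peak_to_peak_fraction / 2.0)
        * np.sin(2.0 * math.pi * spec.frequency * t + spec.phase)
    )
    return val if val.ndim else float(val)


def blood_tissue_susceptibility(
    y, params: SimulationParams, *, absolute: bool = False
):
    """Susceptibility offset of blood at oxygenation ``y``.

    By default this is the blood-minus-tissue difference
    ``delta_chi * hct * (y_tissue - y)`` — positive for venous blood
    (y < y_tissue), negative for arterial.  With ``absolute=True`` the
    water-referenced form ``delta_chi * hct * (1 - y)`` is returned.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("oxygenation y must be in [0, 1]")
    if absolute:
        out = params.delta_chi * params.hct * (1.0 - y)
    else:
        out = params.delta_chi * params.hct * (params.y_tissue - y)
    return out if out.ndim else float(out)


def relaxation_times(
    y: float, compartment: Literal["blood", "tissue"], params: SimulationParams
) -> tuple[float, float]:
    """(T1, T2) in seconds for a compartment at oxygenation ``y``.

    Blood T2 follows the quadratic relaxometry law
    ``1/T2 = A + B*(1-Y) + C*(1-Y)**2`` with coefficients from ``params``;
    tissue T2 is the fixed ``params.t2_tissue``.
    """
    if not 0.0 <= y <= 1.0:
        raise ValueError("oxygenation y must be in [0, 1]")
    if compartment == "blood":
        a, b, c = params.t2_blood_coeffs
        r2 = a + b * (1.0 - y) + c * (1.0 - y) ** 2
        if r2 <= 0:
            raise ValueError(
                f"relaxometry coefficients yield non-positive R2 ({r2}) at y={y}"
            )
        return params.t1_blood, 1.0 / r2
    if compartment == "tissue":
        return params.t1_tissue, params.t2_tissue
    raise ValueError(f"unknown compartment {compartment!r}")


def steady_state_prefactor(t1: float, t2: float, params: SimulationParams) -> float:
    """Steady-state GRE amplitude factor for a compartment.

    Default form keeps the exp(-TE/T2) factor inside the denominator; the
    ``spgr`` form is sin(a)*(1-E1)/(1-cos(a)*E1) * exp(-TE/T2).
    """
    e1 = math.exp(-params.tr / t1)
    e2 = math.exp(-params.te / t2)
    sa, ca = math.sin(params.alpha), math.cos(params.alpha)
    if params.eq4_form == "spgr":
        denom = 1.0 - ca * e1
        extra = e2
    else:
        denom = 1.0 - ca * e1 * e2
        extra = 1.0
    if denom <= 0:
        raise FloatingPointError("non-positive steady-state denominator")
    return sa * (1.0 - e1) / denom * extra


def steady_state_signal(
    s_t2prime: float, t1: float, t2: float, params: SimulationParams
) -> float:
    """Scale a dephasing factor ``s_t2prime`` to a steady-state signal."""
    if not 0.0 <= s_t2prime <= 1.0:
        raise ValueError("s_t2prime must be in [0, 1]")
    return steady_state_prefactor(t1, t2, params) * s_t2prime
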