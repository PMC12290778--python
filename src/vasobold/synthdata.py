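"""Synthetic macro-VANs and pseudo-experimental BOLD runs.

These generators stand in for angiogram-derived vessel networks and
measured resting-state runs so the whole simulation and evaluation chain
can be tested with known ground truth.  Synthetic networks are tubular
vessels of >= 0.8 mm diameter (the detectability floor of the angiograms
being emulated) traced across the field of view; pseudo-experimental runs
add coil-sensitivity-like multiplicative scaling, an optional shared
low-frequency nuisance sinusoid and frame-wise Gaussian noise to a
simulated run.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .metrics import binned_regression, fc_table_to_frame, pairwise_fc_table
from .params import SimulationParams
from .vangeo import LABEL_ARTERY, LABEL_VEIN, VesselVolume
from .vansim import MacroVanScene, SimulatedRun, simulate_van_timeseries

__all__ = [
    "SynthVanSpec",
    "PseudoExperimentSpec",
    "make_synthetic_van",
    "make_pseudo_experimental",
    "recovery_experiment",
]


@dataclass(frozen=True)
class SynthVanSpec:
    """Specification of a synthetic macrovascular network."""

    seed: int = 0
    fov: float = 32.0  # mm, cubic
    voxel_size: float = 0.8  # mm, centreline grid (angiogram-like)
    n_vessels: int = 3
    diameter_range: tuple[float, float] = (0.8, 3.0)
    #: fixed list of (zenith, azimuth) tuples, or "uniform" for random
    #: directions on the sphere
    orientations: Sequence[tuple[float, float]] | Literal["uniform"] = "uniform"
    curvature: float = 0.0  # max direction change, rad per mm
    #: 'alternate' starts with a vein then alternates; or 'all_vein' /
    #: 'all_artery'
    class_rule: Literal["alternate", "all_vein", "all_artery"] = "alternate"

    def __post_init__(self) -> None:
        if self.diameter_range[0] < 0.8:
            raise ValueError("diameters below the 0.8 mm detectability floor")
        if self.diameter_range[0] > self.diameter_range[1]:
            raise ValueError("diameter_range must be (low, high)")
        if self.n_vessels < 1:
            raise ValueError("need at least one vessel")


@dataclass(frozen=True)
class PseudoExperimentSpec:
    """Noise and nuisance model applied on top of a simulated run."""

    seed: int = 0
    noise_sigma: float = 0.05  # frame-wise Gaussian sd, fraction of voxel mean
    nuisance_amplitude: float = 0.0  # fraction of voxel mean, shared sinusoid
    nuisance_frequency: float = 0.03  # Hz
    scaling_range: tuple[float, float] = (0.8, 1.2)  # coil-like gain map
    ar1_rho: float = 0.0  # optional AR(1) noise correlation

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in (-1, 1)")


def _direction(zenith: float, azimuth: float) -> np.ndarray:
    return np.array(
        [
            math.sin(zenith) * math.cos(azimuth),
            math.sin(zenith) * math.sin(azimuth),
            math.cos(zenith),
        ]
    )


def make_synthetic_van(spec: SynthVanSpec) -> VesselVolume:
    """Trace a deterministic synthetic vessel network on a centreline grid.

    Each vessel enters through a random face of the field of view, travels
    along a (possibly gently curving) path until it exits, and deposits
    centreline voxels carrying its diameter and artery/vein label.  On
    overlap the larger diameter wins; veins win label conflicts.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fov / spec.voxel_size))
    centre = np.zeros((n, n, n), dtype=bool)
    diam = np.zeros((n, n, n))
    lab = np.zeros((n, n, n), dtype=np.uint8)

    for vi in range(spec.n_vessels):
        d_mm = float(rng.uniform(*spec.diameter_range))
        if spec.orientations == "uniform":
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            if v[2] < 0:
                v = -v
        else:
            zen, az = spec.orientations[vi % len(spec.orientations)]
            v = _direction(zen, az)
        if spec.class_rule == "all_vein":
            label = LABEL_VEIN
        elif spec.class_rule == "all_artery":
            label = LABEL_ARTERY
        else:
            label = LABEL_VEIN if vi % 2 == 0 else LABEL_ARTERY

        # start near the centre of the FOV, trace both directions until exit
        margin = 0.25 * spec.fov
        start = rng.uniform(margin, spec.fov - margin, size=3)
        step = spec.voxel_size / 2.0
        for placed in _trace_path(start, v, step, spec, rng):
            ijk = np.floor(placed / spec.voxel_size).astype(int)
            if np.any(ijk < 0) or np.any(ijk >= n):
                continue
            t = tuple(ijk)
            centre[t] = True
            diam[t] = max(diam[t], d_mm)  # highest estimate wins on overlap
            lab[t] = max(lab[t], label)  # vein (2) wins label conflicts
    return VesselVolume(centre, diam, lab, spec.voxel_size)


def _trace_path(start, direction, step, spec: SynthVanSpec, rng):
    """Yield points (mm) along a vessel path in both directions from start."""
    for sign in (1.0, -1.0):
        p = start.copy()
        d = sign * direction.copy()
        while np.all(p >= 0) and np.all(p <= spec.fov):
            yield p.copy()
            if spec.curvature > 0:
                # small random rotation of the travel direction
                bend = spec.curvature * step
                perturb = rng.normal(size=3) * bend
                d = d + perturb
                d /= np.linalg.norm(d)
            p = p + d * step


def _scaling_field(shape, rng, lo: float, hi: float) -> np.ndarray:
    """Smooth multiplicative gain map, emulating receive-coil sensitivity."""
    if lo == hi:
        return np.full(shape, lo)
    coarse = rng.uniform(lo, hi, size=(2, 2, 2))
    zoom = [s / 2.0 for s in shape]
    return ndimage.zoom(coarse, zoom, order=1, mode="nearest")


def make_pseudo_experimental(
    run: SimulatedRun | np.ndarray,
    spec: PseudoExperimentSpec,
    tr: float | None = None,
) -> np.ndarray:
    """Degrade a simulated run into a pseudo-experimental 4D volume.

    ``out = gain * (signal + nuisance + noise)`` where the nuisance is a
    sinusoid shared across all voxels and the noise is frame-wise Gaussian
    with sd ``noise_sigma`` times the voxel mean (optionally AR(1)).
    Deterministic given the spec's seed.
    """
    if isinstance(run, SimulatedRun):
        sig = run.signals
        tr = run.params.tr if tr is None else tr
    else:
        sig = np.asarray(run, float)
        if tr is None:
            raise ValueError("tr is required when passing a bare array")
    rng = np.random.default_rng(spec.seed)
    shape, n_frames = sig.shape[:-1], sig.shape[-1]
    vox_mean = sig.mean(axis=-1, keepdims=True)
    out = sig.copy()
    if spec.nuisance_amplitude > 0:
        t = np.arange(n_frames) * tr
        nuis = np.sin(2 * np.pi * spec.nuisance_frequency * t)
        out = out + spec.nuisance_amplitude * vox_mean * nuis
    if spec.noise_sigma > 0:
        eps = rng.standard_normal(sig.shape)
        if spec.ar1_rho != 0.0:
            for k in range(1, n_frames):
                eps[..., k] = (
                    spec.ar1_rho * eps[..., k - 1]
                    + math.sqrt(1 - spec.ar1_rho**2) * eps[..., k]
                )
        out = out + spec.noise_sigma * vox_mean * eps
    gain = _scaling_field(shape, rng, *spec.scaling_range)
    return gain[..., None] * out


def recovery_experiment(
    van_spec: SynthVanSpec,
    noise_levels: Sequence[float] = (0.0, 0.01, 0.05, 0.1, 0.2),
    params: SimulationParams | None = None,
    n_seeds: int = 10,
    n_frames: int | None = None,
    bin_size: int = 10,
    max_lag: int = 5,
    working_voxel: float = 0.2,
    fmri_voxel: float = 4.0,
    nuisance_amplitude: float = 0.0,
    base_seed: int = 1000,
) -> pd.DataFrame:
    """Full-loop parameter recovery: how noise degrades FC prediction.

    Simulates a synthetic VAN once, then for each noise level and seed
    derives a pseudo-experimental run, computes sigma-weighted FC tables
    for both, and regresses measured on predicted FC in fixed-count bins.
    Returns a tidy table with one row per (noise level, seed) holding the
    R^2 and slope.
    """
    params = params or SimulationParams()
    n_frames = n_frames or params.n_frames
    van = make_synthetic_van(van_spec)
    scene = MacroVanScene(
        vessels=van,
        params=params,
        working_voxel=working_voxel,
        fmri_voxel=fmri_voxel,
    )
    run = simulate_van_timeseries(scene, n_frames=n_frames)

    masks: dict[str, np.ndarray] = {}
    vein_mask = (run.fbv > 0) & (run.artery_frac < 0.5)
    artery_mask = (run.fbv > 0) & (run.artery_frac >= 0.5)
    if vein_mask.any():
        masks["vein"] = vein_mask
    if artery_mask.any():
        masks["artery"] = artery_mask
    if not masks:
        raise ValueError("synthetic scene produced no vascular fMRI voxels")

    sim_records = pairwise_fc_table(run.signals, masks, max_lag=max_lag)
    sim_frame = fc_table_to_frame(sim_records)
    sim_frame = sim_frame.sort_values(["voxel_i", "voxel_j"]).reset_index(drop=True)

    rows = []
    for noise in noise_levels:
        for s in range(n_seeds):
            pspec = PseudoExperimentSpec(
                seed=base_seed + 7919 * s + int(round(noise * 1e6)) % 7919,
                noise_sigma=noise,
                nuisance_amplitude=nuisance_amplitude,
            )
            pseudo = make_pseudo_experimental(run, pspec)
            exp_records = pairwise_fc_table(pseudo, masks, max_lag=max_lag)
            exp_frame = fc_table_to_frame(exp_records)
            exp_frame = exp_frame.sort_values(
                ["voxel_i", "voxel_j"]
            ).reset_index(drop=True)
            res = binned_regression(
                sim_frame["weighted"].to_numpy(),
                exp_frame["weighted"].to_numpy(),
                bin_size=bin_size,
            )
            rows.append(
                {
                    "noise_sigma": noise,
                    "seed": pspec.seed,
                    "r_squared": res.r_squared,
                    "slope": res.slope,
                    "n_pairs": len(sim_frame),
                    "n_bins": res.n_bins,
                }
            )
    return pd.DataFrame(rows)
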