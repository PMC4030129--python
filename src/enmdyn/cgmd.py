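"""Coarse-grained Langevin dynamics on the elastic-network potential.

One bead per residue carrying the residue mass, moving on the harmonic
network energy surface coupled to a Langevin thermostat (NVT).  The
integrator is the BAOAB splitting: half-kick, half-drift,
Ornstein–Uhlenbeck velocity refresh, half-drift, half-kick.  With zero
friction it reduces to velocity Verlet and conserves energy; with friction
it samples the canonical configurational distribution with O(dt²) accuracy.

Defaults follow the reduced-MD protocol this reimplements: dt = 0.02 ps,
298 K, uniform γ = 1 kcal mol⁻¹ Å⁻² springs at r_c = 8 Å (set on the
network, not here).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .constants import KB_KCAL, KCAL_TO_AMU_A2_PS2
from .enm import ElasticNetwork, anm_hessian
from .exceptions import IntegrationError, ParameterError, ShapeError
from .structure import Trajectory

logger = logging.getLogger("enmdyn")


@dataclass
class SimulationParams:
    """Langevin run parameters; masses come from the CalphaModel."""

    masses: np.ndarray            # (N,) amu
    n_steps: int
    dt: float = 0.02              # ps
    temperature: float = 298.0    # K
    friction: float = 0.1         # ps⁻¹, weak-coupling thermostat
    save_every: int = 10          # steps between saved frames
    seed: int = 0

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if self.friction < 0:
            raise ParameterError("friction must be non-negative")
        if self.temperature < 0:
            raise ParameterError("temperature must be non-negative")
        if self.save_every < 1:
            raise ParameterError("save_every must be ≥ 1")
        if self.n_steps < 1:
            raise ParameterError("n_steps must be ≥ 1")
        if np.any(self.masses <= 0):
            raise ParameterError("masses must be strictly positive")

    def as_dict(self) -> dict:
        return {"n_steps": int(self.n_steps), "dt": self.dt,
                "temperature": self.temperature, "friction": self.friction,
                "save_every": int(self.save_every), "seed": int(self.seed)}


def max_stable_dt(net: ElasticNetwork, masses: np.ndarray) -> float:
    """Verlet stability bound 2/ω_max from the stiffest Hessian mode."""
    h = anm_hessian(net).entries
    lam_max = float(eigh(h, eigvals_only=True,
                         subset_by_index=[h.shape[0] - 1, h.shape[0] - 1])[0])
    if lam_max <= 0:
        return np.inf
    omega_max = np.sqrt(lam_max * KCAL_TO_AMU_A2_PS2 / np.min(masses))
    return 2.0 / omega_max


def run_langevin(net: ElasticNetwork, params: SimulationParams,
                 init_coords: np.ndarray | None = None) -> Trajectory:
    """Integrate BAOAB Langevin dynamics and return the saved trajectory.

    Initial velocities are Maxwell–Boltzmann at ``params.temperature``.
    Center-of-mass translation (and net momentum) is removed at every save
    point.  The trajectory is bit-reproducible from (network, params).
    """
    n = net.n_beads
    if len(params.masses) != n:
        raise ShapeError(
            f"{len(params.masses)} masses for a {n}-bead network")
    coords = (net.ref_coords if init_coords is None
              else np.asarray(init_coords, dtype=float)).copy()
    if coords.shape != (n, 3):
        raise ShapeError(f"init_coords must be ({n}, 3), got {coords.shape}")

    dt = params.dt
    dt_bound = max_stable_dt(net, params.masses)
    if dt >= dt_bound:
        raise IntegrationError(
            f"dt = {dt} ps unstable: stability bound 2/ω_max = "
            f"{dt_bound:.4g} ps for this network")

    m = params.masses[:, None]                       # (N, 1) amu
    kT_kin = KB_KCAL * params.temperature * KCAL_TO_AMU_A2_PS2  # amu Å²/ps²
    rng = np.random.default_rng(params.seed)
    vel = rng.normal(0.0, np.sqrt(kT_kin / m), size=(n, 3))

    # O-step coefficients (exact OU solution over dt)
    c1 = np.exp(-params.friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT_kin / m)       # (N, 1)

    # precomputed edge arrays for a lean force kernel
    ei, ej = net.edges[:, 0], net.edges[:, 1]
    pg, d0 = net.pair_gamma, net.ref_dist
    acc_fac = KCAL_TO_AMU_A2_PS2 / m                 # force -> Å/ps²

    def acceleration(x):
        delta = x[ei] - x[ej]
        dist = np.sqrt(np.einsum("ij,ij->i", delta, delta))
        f = np.zeros_like(x)
        pair = (-pg * (dist - d0) / dist)[:, None] * delta
        np.add.at(f, ei, pair)
        np.add.at(f, ej, -pair)
        return f * acc_fac

    n_frames = params.n_steps // params.save_every
    frames = np.empty((n_frames, n, 3))
    velocities = np.empty((n_frames, n, 3))
    total_mass = params.masses.sum()
    ref_com = (params.masses[:, None] * net.ref_coords).sum(0) / total_mass

    acc = acceleration(coords)
    frame = 0
    half = 0.5 * dt
    stochastic = params.friction > 0 and params.temperature > 0
    for step in range(1, params.n_steps + 1):
        vel += half * acc                            # B
        coords += half * vel                         # A
        if stochastic:
            vel = c1 * vel + c2 * rng.standard_normal((n, 3))  # O
        elif params.friction > 0:
            vel *= c1
        coords += half * vel                         # A
        acc = acceleration(coords)
        vel += half * acc                            # B
        if step % params.save_every == 0:
            if not np.all(np.isfinite(coords)):
                raise IntegrationError(f"trajectory diverged at step {step}")
            com = (params.masses[:, None] * coords).sum(0) / total_mass
            coords -= com - ref_com
            mom = (params.masses[:, None] * vel).sum(0) / total_mass
            vel -= mom
            frames[frame] = coords
            velocities[frame] = vel
            frame += 1

    meta = {"params": params.as_dict(), "integrator": "baoab",
            "r_c": net.r_c, "gamma": net.gamma,
            "weight_exponent": net.weight_exponent,
            "masses": params.masses.copy()}
    return Trajectory(frames=frames, dt=dt * params.save_every,
                      origin="cgmd", velocities=velocities, meta=meta)


def kinetic_temperature(velocities: np.ndarray | Trajectory,
                        masses: np.ndarray | None = None):
    """Instantaneous kinetic temperature, K.

    T_kin = Σ m v² / (3N k_B).  For a single (N, 3) velocity array a scalar
    is returned; for a trajectory (or an (F, N, 3) array) a per-frame series,
    whose mean is the running thermostat check.
    """
    if isinstance(velocities, Trajectory):
        if velocities.velocities is None:
            raise ParameterError("trajectory carries no velocities")
        if masses is None:
            masses = velocities.meta.get("masses")
        v = velocities.velocities
    else:
        v = np.asarray(velocities, dtype=float)
    if masses is None:
        raise ParameterError("masses are required")
    masses = np.asarray(masses, dtype=float)
    v2 = np.sum(v ** 2, axis=-1)                     # (..., N)
    ke = 0.5 * np.sum(masses * v2, axis=-1) / KCAL_TO_AMU_A2_PS2  # kcal/mol
    n = v.shape[-2]
    t = 2.0 * ke / (3.0 * n * KB_KCAL)
    return float(t) if np.ndim(t) == 0 else t
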