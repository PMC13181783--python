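"""Synthetic inputs with known statistics: stochastic frequency
trajectories (Ornstein–Uhlenbeck and two-timescale Kubo processes) and
random water boxes, plus a Brownian box-evolution step for building
time-correlated synthetic trajectories.

The OU update uses the exact discretization
δω_{k+1} = δω_k·e^{−Δt/τ} + σ·sqrt(1 − e^{−2Δt/τ})·ξ_k with a stationary
start, so the analytic autocorrelation σ²·exp(−t/τ) holds at any step
size. Two independent OU components summed give the two-timescale Kubo
process with C(t) = σ₁²e^{−t/τ₁} + σ₂²e^{−t/τ₂}; defaults sit in the
physical regimes of water spectral diffusion (fast hydrogen-bond
making/breaking at 50–400 fs, network reorganization at 0.7–1.2 ps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import Frame, minimum_image
from .observables import ModeSeries

__all__ = [
    "KuboParams",
    "SyntheticBoxParams",
    "simulate_ou",
    "simulate_two_timescale",
    "generate_water_box",
    "evolve_water_box",
]

R_OH = 0.9572  # Å, rigid water geometry
THETA_HOH = np.deg2rad(104.52)

try:  # compiled RSA kernel; plain numpy fallback below
    from numba import njit

    @njit(cache=True)
    def _rsa_scan(cand, accepted, n_acc, n_target, min_oo2, box):
        """Greedily accept candidates with no min-image conflict; returns count."""
        for i in range(cand.shape[0]):
            ok = True
            for j in range(n_acc):
                d2 = 0.0
                for k in range(3):
                    d = cand[i, k] - accepted[j, k]
                    d -= box * round(d / box)
                    d2 += d * d
                if d2 < min_oo2:
                    ok = False
                    break
            if ok:
                accepted[n_acc] = cand[i]
                n_acc += 1
                if n_acc == n_target:
                    break
        return n_acc

except ImportError:  # pragma: no cover - numba is normally available
    def _rsa_scan(cand, accepted, n_acc, n_target, min_oo2, box):
        min_oo = np.sqrt(min_oo2)
        for i in range(len(cand)):
            if n_acc:
                d = np.linalg.norm(
                    minimum_image(accepted[:n_acc] - cand[i], np.full(3, box)), axis=1
                )
                if d.min() < min_oo:
                    continue
            accepted[n_acc] = cand[i]
            n_acc += 1
            if n_acc == n_target:
                break
        return n_acc


@dataclass(frozen=True)
class KuboParams:
    """Two-timescale Kubo process parameters."""

    mean: float = 2500.0  # cm⁻¹
    sigma1: float = 60.0  # cm⁻¹
    tau1: float = 0.1  # ps
    sigma2: float = 40.0  # cm⁻¹
    tau2: float = 1.0  # ps
    dt_fs: float = 50.0
    n_points: int = 1000
    replicas: int = 12
    seed: int = 0
    label: str = "OD"

    def __post_init__(self):
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if min(self.tau1, self.tau2, self.dt_fs) <= 0:
            raise ValueError("time constants and dt must be positive")


@dataclass(frozen=True)
class SyntheticBoxParams:
    """Random-sequential-insertion water box parameters."""

    n_waters: int = 200
    box_length: float = 18.2  # Å → bulk-water number density
    min_oo: float = 2.6  # Å
    seed: int = 0

    def __post_init__(self):
        vol = self.box_length**3
        excl = self.n_waters * 4.0 / 3.0 * np.pi * (self.min_oo / 2) ** 3
        if excl >= vol:
            raise ValueError("packing infeasible: exclusion volume exceeds box volume")


def simulate_ou(
    sigma: float, tau_ps: float, dt_fs: float, n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck fluctuation series δω (exact update)."""
    if sigma < 0 or tau_ps <= 0 or dt_fs <= 0 or n <= 0:
        raise ValueError("parameters must be positive (sigma may be zero)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rho = np.exp(-dt_fs / 1000.0 / tau_ps)
    noise = sigma * np.sqrt(1.0 - rho**2)
    x = np.empty(n)
    x[0] = sigma * rng.standard_normal()
    xi = rng.standard_normal(n - 1)
    for k in range(1, n):
        x[k] = x[k - 1] * rho + noise * xi[k - 1]
    return x


def simulate_two_timescale(params: KuboParams) -> ModeSeries:
    """Sum of two independent OU components plus the mean, per replica.

    Each (replica, component) pair draws from its own child RNG stream
    seeded as (seed, replica, component), so setting σ₂ = 0 reproduces the
    single-component series bit for bit.
    """
    reps, times, freqs = [], [], []
    dt_ps = params.dt_fs / 1000.0
    for r in range(params.replicas):
        x = np.zeros(params.n_points)
        for comp, (sig, tau) in enumerate(
            ((params.sigma1, params.tau1), (params.sigma2, params.tau2))
        ):
            if sig > 0:
                rng = np.random.default_rng([params.seed, r, comp])
                x += simulate_ou(sig, tau, params.dt_fs, params.n_points, rng)
        reps.append(np.full(params.n_points, r))
        times.append(dt_ps * (1 + np.arange(params.n_points)))
        freqs.append(params.mean + x)
    n_tot = params.replicas * params.n_points
    return ModeSeries(
        params.label,
        np.concatenate(reps),
        np.concatenate(times),
        np.concatenate(freqs),
        np.ones(n_tot),
        np.zeros(n_tot, int),
        params.dt_fs,
    )


def _random_water(o: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rigid water at oxygen position ``o`` with a random orientation."""
    # first O–H along a uniformly random direction
    v = rng.standard_normal(3)
    u1 = v / np.linalg.norm(v)
    # second O–H at the HOH angle, random azimuth around u1
    w = rng.standard_normal(3)
    perp = w - np.dot(w, u1) * u1
    perp /= np.linalg.norm(perp)
    u2 = np.cos(THETA_HOH) * u1 + np.sin(THETA_HOH) * perp
    return np.vstack([o, o + R_OH * u1, o + R_OH * u2])


def generate_water_box(params: SyntheticBoxParams, time_ps: float = 0.0) -> Frame:
    """Random water box by sequential insertion with an O–O exclusion radius.

    Oxygen positions are drawn uniformly and rejected if any minimum-image
    O–O distance falls below ``min_oo``; each accepted water gets the rigid
    gas-phase geometry at a random orientation. Deterministic given the
    seed.
    """
    rng = np.random.default_rng(params.seed)
    box = np.full(3, params.box_length)
    # bulk density with a 2.6 Å exclusion sits near the random-insertion
    # jamming limit; candidates are drawn in chunks and scanned by the
    # compiled kernel, with a generous total budget so failures stay rare
    max_attempts = 400_000
    chunk = 8192
    accepted = np.empty((params.n_waters, 3))
    n_acc = 0
    drawn = 0
    while n_acc < params.n_waters:
        if drawn >= max_attempts:
            raise RuntimeError(
                f"failed to insert water {n_acc + 1}/{params.n_waters} after "
                f"{max_attempts} attempts; lower the density or min_oo"
            )
        cand = rng.uniform(0.0, params.box_length, (chunk, 3))
        drawn += chunk
        n_acc = int(_rsa_scan(cand, accepted, n_acc, params.n_waters,
                              params.min_oo**2, params.box_length))
    mol_coords = [_random_water(o, rng) for o in accepted]
    coords = np.vstack(mol_coords)
    elements = np.array(["O", "H", "H"] * params.n_waters, dtype=object)
    return Frame(elements, coords, box, time_ps)


def evolve_water_box(
    frame: Frame,
    rng: np.random.Generator,
    step_sigma: float = 0.12,  # Å per step, rigid-body translation
    rot_sigma: float = 0.08,  # rad per step
    min_oo: float = 2.6,
    time_ps: float | None = None,
) -> Frame:
    """One Brownian step of a synthetic water-box trajectory.

    Each water is rigid-body translated by an isotropic Gaussian step and
    rotated by a small random rotation about its oxygen; moves violating
    the O–O exclusion distance are rejected (the molecule keeps its old
    position). This produces time-correlated solvation environments for
    end-to-end tests; it is not molecular dynamics.
    """
    n_mol = frame.n_atoms // 3
    coords = frame.coords.copy()
    oxygens = coords[0::3].copy()
    box = frame.box
    for i in range(n_mol):
        old = coords[3 * i : 3 * i + 3]
        shift = rng.normal(0.0, step_sigma, 3)
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = rng.normal(0.0, rot_sigma)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        new_o = old[0] + shift
        new = np.vstack([new_o, new_o + (old[1] - old[0]) @ R.T, new_o + (old[2] - old[0]) @ R.T])
        others = np.delete(oxygens, i, axis=0)
        d = np.linalg.norm(minimum_image(others - new_o, box), axis=1)
        if d.min() >= min_oo:
            coords[3 * i : 3 * i + 3] = new
            oxygens[i] = new_o
    return Frame(
        frame.elements, coords, box,
        frame.time_ps if time_ps is None else time_ps,
    )
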