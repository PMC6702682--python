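"""Stationary points, numerical Hessians, harmonic analysis and trajectories.

Frequencies follow the quantum-chemistry printing convention: eigenvalues
lambda of the mass-weighted Hessian are reported as sign(lambda) *
sqrt(|lambda|), so imaginary (transition-state) modes appear as negative
wavenumbers.  In the package's natural unit system (energies cm^-1, hbar=1,
see :mod:`sopes.units`) the conversion factor is unity; for Hessians in
hartree/(bohr^2 amu) the CODATA factor of :data:`sopes.units.AU_AMU_FREQ_CM1`
applies.

Classical validation trajectories use velocity-Verlet with the time step
given in femtoseconds and microcanonical normal-mode initial conditions:
the requested vibrational energy is split over the modes by a seeded
uniform-simplex draw and each mode is given a harmonic displacement and
velocity at a random phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from sopes import units
from sopes.surfaces import SurfaceBackend

__all__ = [
    "PointKind",
    "StationaryPoint",
    "Trajectory",
    "numerical_gradient",
    "numerical_hessian",
    "harmonic_frequencies",
    "refine_stationary",
    "normal_mode_sample",
    "propagate_verlet",
    "NonConvergenceError",
    "WrongIndexError",
]


class PointKind(str, Enum):
    MINIMUM = "minimum"
    TS = "ts"
    HIGHER = "higher"


class NonConvergenceError(RuntimeError):
    """Stationary-point refinement did not converge within the iteration cap."""


class WrongIndexError(RuntimeError):
    """Refinement converged, but to a point of a different Hessian index."""

    def __init__(self, message, point):
        super().__init__(message)
        self.point = point


@dataclass
class StationaryPoint:
    geometry: np.ndarray
    energy: float
    hessian: np.ndarray
    frequencies: np.ndarray  # cm^-1, imaginary modes negative
    modes: np.ndarray        # columns: mass-weighted normal modes
    kind: PointKind
    masses: np.ndarray | None = None

    @property
    def n_imaginary(self) -> int:
        return int(np.sum(self.frequencies < 0.0))


@dataclass
class Trajectory:
    frames: list  # (time_fs, geometry, potential, kinetic)
    total_energy: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def energies(self) -> np.ndarray:
        """(n_frames, 3) array of potential, kinetic, total energy."""
        return np.array([[p, k, p + k] for _, _, p, k in self.frames])

    def geometries(self) -> np.ndarray:
        return np.array([g for _, g, _, _ in self.frames])

    def times_fs(self) -> np.ndarray:
        return np.array([t for t, _, _, _ in self.frames])

    @property
    def drift(self) -> float:
        """Max relative total-energy deviation over the trajectory.

        For a symplectic integrator this is a bounded oscillation of order
        (omega dt)^2, not an accumulating error; see ``secular_drift``.
        """
        tot = self.energies()[:, 2]
        scale = max(abs(tot[0]), 1e-300)
        return float(np.max(np.abs(tot - tot[0])) / scale)

    def secular_drift(self, window: float = 0.1) -> float:
        """Accumulated relative energy drift: windowed end-vs-start mean.

        Compares the mean total energy over the last ``window`` fraction of
        frames with the first, cancelling the bounded symplectic
        oscillation and exposing any genuine secular energy loss/gain.
        """
        tot = self.energies()[:, 2]
        n = max(1, int(window * tot.size))
        scale = max(abs(tot[0]), 1e-300)
        return float(abs(tot[-n:].mean() - tot[:n].mean()) / scale)

    def export_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame({"time_fs": self.times_fs()})
        df[["potential", "kinetic", "total"]] = self.energies()
        df.to_csv(path, index=False)


def _grad(backend: SurfaceBackend, geometry, zeta, step=1e-5):
    try:
        return backend.gradient(geometry, zeta)
    except NotImplementedError:
        return numerical_gradient(backend, geometry, zeta, step)


def numerical_gradient(backend, geometry, zeta=None, step: float = 1e-5) -> np.ndarray:
    g = np.asarray(geometry, dtype=float)
    out = np.empty_like(g)
    for i in range(g.size):
        e = np.zeros_like(g)
        e[i] = step
        out[i] = (backend.energy(g + e, zeta) - backend.energy(g - e, zeta)) / (2 * step)
    return out


def numerical_hessian(backend, geometry, zeta=None, step: float = 1e-3,
                      richardson: bool = False) -> np.ndarray:
    """Central-difference Hessian from energies, symmetrized as (H + H^T)/2.

    With ``richardson`` the stencil is evaluated at step and step/2 and
    extrapolated, removing the leading O(step^2) error.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if richardson:
        h1 = numerical_hessian(backend, geometry, zeta, step, False)
        h2 = numerical_hessian(backend, geometry, zeta, step / 2.0, False)
        return (4.0 * h2 - h1) / 3.0
    g = np.asarray(geometry, dtype=float)
    n = g.size
    h = np.empty((n, n))
    e0 = backend.energy(g, zeta)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        h[i, i] = (backend.energy(g + ei, zeta) - 2 * e0 + backend.energy(g - ei, zeta)) / step**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = step
            h[i, j] = h[j, i] = (
                backend.energy(g + ei + ej, zeta) - backend.energy(g + ei - ej, zeta)
                - backend.energy(g - ei + ej, zeta) + backend.energy(g - ei - ej, zeta)
            ) / (4 * step**2)
    return 0.5 * (h + h.T)


def harmonic_frequencies(hessian: np.ndarray, masses: np.ndarray,
                         unit_system: str = "natural",
                         return_modes: bool = False):
    """Harmonic frequencies (cm^-1, ascending; imaginary as negative reals).

    ``unit_system``: "natural" (package toy units, factor 1) or "au_amu"
    (Hessian in hartree/bohr^2, masses in amu).
    """
    hessian = np.asarray(hessian, dtype=float)
    if not np.allclose(hessian, hessian.T, atol=1e-8 * max(1.0, np.abs(hessian).max())):
        raise ValueError("Hessian not symmetric within tolerance")
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    conv = {"natural": 1.0, "au_amu": units.AU_AMU_FREQ_CM1}[unit_system]
    inv_sqrt_m = 1.0 / np.sqrt(masses)
    mw = hessian * np.outer(inv_sqrt_m, inv_sqrt_m)
    lam, vec = np.linalg.eigh(0.5 * (mw + mw.T))
    freqs = np.sign(lam) * np.sqrt(np.abs(lam)) * conv
    order = np.argsort(freqs)
    if return_modes:
        return freqs[order], vec[:, order]
    return freqs[order]


def _analyze(backend, zeta, geometry, masses, hessian_step):
    try:
        h = backend.hessian(geometry, zeta)
    except NotImplementedError:
        h = numerical_hessian(backend, geometry, zeta, hessian_step)
    freqs, modes = harmonic_frequencies(h, masses, return_modes=True)
    n_neg = int(np.sum(freqs < 0.0))
    kind = PointKind.MINIMUM if n_neg == 0 else (
        PointKind.TS if n_neg == 1 else PointKind.HIGHER)
    return h, freqs, modes, kind


def refine_stationary(backend: SurfaceBackend, zeta, guess, kind: PointKind | str,
                      masses=None, tol: float = 1e-8, max_iter: int = 60,
                      hessian_step: float = 1e-3) -> StationaryPoint:
    """Newton refinement of a stationary point from a guess geometry.

    Iterates x <- x - H^-1 g until max|gradient| < tol; the requested
    ``kind`` is validated against the Hessian signature at convergence
    (a mismatch raises :class:`WrongIndexError` carrying the point).
    """
    kind = PointKind(kind)
    x = np.asarray(guess, dtype=float).copy()
    masses = np.ones(x.size) if masses is None else np.asarray(masses, float)
    for _ in range(max_iter):
        g = _grad(backend, x, zeta)
        if np.max(np.abs(g)) < tol:
            break
        try:
            h = backend.hessian(x, zeta)
        except NotImplementedError:
            h = numerical_hessian(backend, x, zeta, hessian_step)
        try:
            dx = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(h, g, rcond=None)[0]
        # trust-region-like cap keeps Newton from leaving the basin
        norm = np.linalg.norm(dx)
        if norm > 0.5:
            dx *= 0.5 / norm
        x = x - dx
    else:
        raise NonConvergenceError(
            f"no convergence in {max_iter} Newton iterations (|g|max="
            f"{np.max(np.abs(_grad(backend, x, zeta))):.3g})")
    h, freqs, modes, found = _analyze(backend, zeta, x, masses, hessian_step)
    sp = StationaryPoint(x, float(backend.energy(x, zeta)), h, freqs, modes,
                         found, masses=masses)
    if found != kind:
        raise WrongIndexError(
            f"refinement converged to a {found.value} ({sp.n_imaginary} imaginary "
            f"modes), expected {kind.value}", sp)
    return sp


def normal_mode_sample(sp: StationaryPoint, total_energy: float, seed: int,
                       rng: np.random.Generator | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Microcanonical normal-mode initial conditions at a minimum.

    The vibrational energy is partitioned over all modes by a seeded
    uniform-simplex draw; each mode receives a classical harmonic
    displacement/velocity at a uniformly random phase.  Returns the
    displaced geometry and velocities (non-mass-weighted).
    """
    if sp.kind != PointKind.MINIMUM:
        raise ValueError("normal-mode sampling requires a minimum")
    if total_energy <= 0:
        raise ValueError("total_energy must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    n = sp.frequencies.size
    # uniform simplex partition via sorted-uniform spacings
    cuts = np.sort(rng.uniform(0.0, 1.0, n - 1)) if n > 1 else np.array([])
    parts = np.diff(np.concatenate([[0.0], cuts, [1.0]])) * total_energy
    masses = np.ones(n) if sp.masses is None else sp.masses
    xi = np.zeros(n)   # mass-weighted displacements
    vxi = np.zeros(n)  # mass-weighted velocities
    for i in range(n):
        omega = sp.frequencies[i]
        if omega <= 0:
            continue
        amp = np.sqrt(2.0 * parts[i]) / omega
        theta = rng.uniform(0.0, 2.0 * np.pi)
        xi[i] = amp * np.sin(theta)
        vxi[i] = amp * omega * np.cos(theta)
    dq = (sp.modes @ xi) / np.sqrt(masses)
    v = (sp.modes @ vxi) / np.sqrt(masses)
    return sp.geometry + dq, v


def propagate_verlet(backend: SurfaceBackend, zeta, state, dt_fs: float,
                     n_steps: int, masses=None) -> Trajectory:
    """Velocity-Verlet propagation; frames stored every step, t=0 included.

    ``state`` is (geometry, velocities) with velocities in natural units per
    natural time.  A backend failure mid-trajectory returns the partial
    trajectory with an ``error`` mark in ``meta``.
    """
    if dt_fs <= 0:
        raise ValueError("dt must be positive")
    q, v = (np.asarray(a, dtype=float).copy() for a in state)
    masses = np.ones(q.size) if masses is None else np.asarray(masses, float)
    dt = units.fs_to_natural(dt_fs)
    frames, meta = [], {}

    def record(step):
        pe = backend.energy(q, zeta)
        ke = 0.5 * float(np.sum(masses * v**2))
        frames.append((step * dt_fs, q.copy(), pe, ke))

    try:
        acc = -_grad(backend, q, zeta) / masses
        record(0)
        for step in range(1, n_steps + 1):
            q += v * dt + 0.5 * acc * dt**2
            acc_new = -_grad(backend, q, zeta) / masses
            v += 0.5 * (acc + acc_new) * dt
            acc = acc_new
            record(step)
    except Exception as exc:  # partial trajectory with error mark
        meta["error"] = f"backend failure at step {len(frames)}: {exc}"
    total = frames[0][2] + frames[0][3] if frames else float("nan")
    traj = Trajectory(frames, total, meta)
    traj.meta.setdefault("dt_fs", dt_fs)
    traj.meta["relative_drift"] = traj.drift if frames else float("nan")
    return traj
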