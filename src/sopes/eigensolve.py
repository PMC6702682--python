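"""Grid-based vibrational eigensolver for low-dimensional (<= 3D) potentials.

The Hamiltonian on a direct-product DVR grid is

    H = sum_kappa (1/2 m_kappa) T^(kappa) x I + diag(V)

with T the mass-free second-derivative DVR matrix of each grid and V the
potential on the grid (a Tucker potential, a dense value tensor or a
callable on grid indices).  Eigenlevels are reported relative to the ground
state; the absolute ground-state energy is the zero-point energy (ZPE).

Comparison metrics between level lists follow the benchmark-table
convention: the RMSE is taken over all reported rows including the leading
zero (ground-state) row, and the MAD is the mean absolute deviation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh

from sopes.grids import DVRGrid, primitive_grid_size
from sopes.sop_tensor import TuckerPotential

__all__ = [
    "GridHamiltonian",
    "EigenReport",
    "build_hamiltonian",
    "lowest_eigenpairs",
    "eigen_rmse",
    "autocorrelation_spectrum",
]

#: largest direct-product dimension the builder accepts
DIMENSION_CAP = 20_000
#: below this dimension a dense symmetric solver is used
_DENSE_LIMIT = 2_500


@dataclass
class GridHamiltonian:
    grids: list[DVRGrid]
    masses: np.ndarray
    values: np.ndarray           # potential on the grid
    matrix: sp.spmatrix          # sparse symmetric Hamiltonian

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EigenReport:
    levels: np.ndarray           # cm^-1, relative to the ground state
    zpe: float                   # absolute ground-state energy
    comparison: dict | None = None
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame({"level": np.arange(self.levels.size),
                           "energy_cm1": self.levels})
        with open(path, "w") as fh:
            fh.write(f"# zpe_cm1 = {self.zpe:.6f}\n")
            df.to_csv(fh, index=False)


def _potential_tensor(potential, shape) -> np.ndarray:
    if isinstance(potential, TuckerPotential):
        if potential.shape != tuple(shape):
            raise ValueError("Tucker potential grids do not match the Hamiltonian grids")
        return potential.full_tensor()
    if callable(potential):
        out = np.empty(shape)
        for idx in itertools.product(*(range(n) for n in shape)):
            out[idx] = potential(idx)
        return out
    arr = np.asarray(potential, dtype=float)
    if arr.shape != tuple(shape):
        raise ValueError(f"potential shape {arr.shape} does not match grids {tuple(shape)}")
    return arr


def build_hamiltonian(grids: list[DVRGrid], masses, potential,
                      cap: int = DIMENSION_CAP) -> GridHamiltonian:
    """Assemble the sparse product-grid Hamiltonian."""
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    shape = tuple(g.n_points for g in grids)
    dim = primitive_grid_size(grids)
    if dim > cap:
        raise ValueError(f"grid dimension {dim} exceeds the cap {cap}")
    values = _potential_tensor(potential, shape)
    h = sp.diags(values.ravel()).tolil()
    for k, g in enumerate(grids):
        left = int(np.prod(shape[:k], dtype=int))
        right = int(np.prod(shape[k + 1:], dtype=int))
        term = sp.kron(sp.identity(left),
                       sp.kron(sp.csr_matrix(g.kinetic / (2.0 * masses[k])),
                               sp.identity(right)))
        h = h + term
    h = h.tocsr()
    asym = abs(h - h.T).max()
    if asym > 1e-10 * max(1.0, abs(h).max()):
        raise ValueError("assembled Hamiltonian is not Hermitian within tolerance")
    return GridHamiltonian(list(grids), masses, values, h)


def lowest_eigenpairs(ham: GridHamiltonian, k: int,
                      return_vectors: bool = False):
    """k lowest eigenvalues (relative to the ground state) and the ZPE."""
    dim = ham.dimension
    if k >= dim:
        raise ValueError(f"k={k} too large for dimension {dim}")
    if dim <= _DENSE_LIMIT:
        w, v = np.linalg.eigh(ham.matrix.toarray())
        w, v = w[:k], v[:, :k]
    else:
        w, v = eigsh(ham.matrix, k=k, which="SA")
        order = np.argsort(w)
        w, v = w[order], v[:, order]
    report = EigenReport(levels=w - w[0], zpe=float(w[0]),
                         meta={"dimension": dim, "k": int(k)})
    if return_vectors:
        return report, w, v
    return report


def eigen_rmse(levels, reference_levels) -> tuple[float, float]:
    """(RMSE, mean absolute deviation) between two level lists.

    Both metrics run over every entry, including the leading zero
    ground-state row.
    """
    a = np.asarray(levels, dtype=float)
    b = np.asarray(reference_levels, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    d = a - b
    return float(np.sqrt(np.mean(d**2))), float(np.mean(np.abs(d)))


def autocorrelation_spectrum(psi0: np.ndarray, ham: GridHamiltonian,
                             t_max: float, dt: float) -> dict:
    """Vibrational spectrum from the autocorrelation of a propagated state.

    The initial amplitude vector is propagated by spectral expansion in the
    Hamiltonian's eigenpairs, a(t) = <psi(0)|psi(t)> = sum |c_n|^2
    exp(-i E_n t); the windowed (Hann) Fourier transform is returned with a
    list of local-maximum peak positions.  Requires a normalized input.
    """
    psi0 = np.asarray(psi0, dtype=complex).ravel()
    if abs(np.linalg.norm(psi0) - 1.0) > 1e-8:
        raise ValueError("initial amplitude vector must be normalized")
    dim = ham.dimension
    if dim > _DENSE_LIMIT:
        raise ValueError("spectral propagation requires a dense-solvable dimension")
    w, v = np.linalg.eigh(ham.matrix.toarray())
    coeff2 = np.abs(v.conj().T @ psi0) ** 2
    times = np.arange(0.0, t_max, dt)
    auto = (coeff2[None, :] * np.exp(-1j * np.outer(times, w))).sum(axis=1)
    window = np.hanning(times.size)
    # a(t) carries exp(-i E t); transform against exp(-i omega t) puts the
    # peaks at +E when the signal is conjugated first
    spec = np.fft.fft(np.conj(auto) * window)
    freqs = 2.0 * np.pi * np.fft.fftfreq(times.size, d=dt)
    pos = freqs >= 0
    freqs, inten = freqs[pos], np.abs(spec[pos])
    peaks = [float(freqs[i]) for i in range(1, freqs.size - 1)
             if inten[i] > inten[i - 1] and inten[i] >= inten[i + 1]
             and inten[i] > 1e-3 * inten.max()]
    return {"frequencies": freqs, "intensity": inten, "peaks": peaks,
            "eigen_weights": coeff2}
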