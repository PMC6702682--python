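"""DVR primitive grids, kinetic-energy matrices and multigrid subgrids.

Two DVR families are provided.  The harmonic-oscillator (Hermite) DVR is
parametrized by (N, first, last): the unit Gauss-Hermite nodes (eigenvalues
of the position operator in the first N oscillator eigenfunctions) are
affinely mapped so that the outermost nodes coincide with the requested
range.  The cosine DVR uses the N equidistant midpoints of the range with
the {cos(j pi (x-a)/L)} basis (Neumann boundary conditions).

The ``kinetic`` matrix stored on a grid is the DVR representation of the
mass-free operator -d^2/dq^2; a kinetic-energy operator is obtained as
kinetic/(2m).

Multigrid bookkeeping: given a stride k, the coarse index set of each DOF is
the arithmetic progression {0, k, 2k, ...} (optionally completed with the
last index), and the partial grid of DOF kappa is full along kappa and
coarse along every other DOF.  Indices are 0-based, ranges closed, angles in
radians.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DVRGrid",
    "MultiGrid",
    "build_dvr",
    "harmonic_dvr_natural",
    "primitive_grid_size",
    "make_multigrid",
]


@dataclass(frozen=True)
class DVRGrid:
    """A one-dimensional DVR primitive grid."""

    kind: str
    n_points: int
    range: tuple[float, float]
    points: np.ndarray
    kinetic: np.ndarray
    #: name of the degree of freedom (bookkeeping only)
    name: str = ""
    #: extra metadata (e.g. the natural harmonic length scale)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_points >= 2 and not np.all(np.diff(self.points) > 0):
            raise ValueError("DVR points must be strictly increasing")
        if not np.allclose(self.kinetic, self.kinetic.T, atol=1e-10):
            raise ValueError("kinetic matrix must be symmetric")

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "n_points": int(self.n_points),
            "first": float(self.range[0]),
            "last": float(self.range[1]),
        }


def _hermite_unit_dvr(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit (omega = m = hbar = 1) Hermite DVR nodes and -d^2/dq^2 matrix.

    The position operator in the first n oscillator eigenfunctions is
    tridiagonal with off-diagonal sqrt((i+1)/2); its eigenvalues are the
    Gauss-Hermite nodes and its eigenvectors define the DVR transform.  The
    momentum-squared operator in the same basis has diagonal (2i+1)/2 and
    second off-diagonal -sqrt((i+1)(i+2))/2.
    """
    if n == 1:
        return np.zeros(1), np.array([[0.5]])
    i = np.arange(n - 1)
    q = np.diag(np.sqrt((i + 1) / 2.0), 1)
    q = q + q.T
    nodes, u = np.linalg.eigh(q)
    p2 = np.diag((2.0 * np.arange(n) + 1.0) / 2.0)
    j = np.arange(n - 2)
    off2 = -np.sqrt((j + 1.0) * (j + 2.0)) / 2.0
    p2 += np.diag(off2, 2) + np.diag(off2, -2)
    kin = u.T @ p2 @ u
    return nodes, 0.5 * (kin + kin.T)


def _cosine_dvr(n: int, first: float, last: float) -> tuple[np.ndarray, np.ndarray]:
    """Cosine-basis DVR: equidistant midpoints, -d^2/dx^2 from {cos(j pi s)}."""
    length = last - first
    i = np.arange(n)
    points = first + length * (i + 0.5) / n
    # orthogonal DCT-like transform between basis j and grid i
    u = np.cos(np.outer(np.pi * (i + 0.5) / n, np.arange(n)))
    norm = np.full(n, math.sqrt(2.0 / n))
    norm[0] = math.sqrt(1.0 / n)
    u = u * norm  # u[i, j] = <grid i | basis j>
    eig = (np.arange(n) * np.pi / length) ** 2
    kin = (u * eig) @ u.T
    return points, 0.5 * (kin + kin.T)


def build_dvr(kind: str, n_points: int, range: tuple[float, float], name: str = "") -> DVRGrid:
    """Construct a DVR grid of the given family on a closed range.

    Parameters
    ----------
    kind : {"harmonic", "cosine"}
        DVR family ("HO"/"cos" aliases accepted).
    n_points : int
        Number of grid points, >= 1.
    range : (first, last)
        Coordinate range; for the harmonic DVR the outermost nodes coincide
        with it, for the cosine DVR the points are interior midpoints.
    """
    first, last = float(range[0]), float(range[1])
    if n_points < 1:
        raise ValueError(f"n_points must be positive, got {n_points}")
    if not first < last:
        raise ValueError(f"degenerate range {range!r}")
    kind_norm = {"harmonic": "harmonic", "ho": "harmonic", "cosine": "cosine", "cos": "cosine"}.get(
        str(kind).lower()
    )
    if kind_norm is None:
        raise ValueError(f"unknown DVR kind {kind!r}")

    if kind_norm == "harmonic":
        nodes, kin_unit = _hermite_unit_dvr(n_points)
        if n_points == 1:
            points = np.array([(first + last) / 2.0])
            scale = 1.0
        else:
            scale = (last - first) / (nodes[-1] - nodes[0])
            points = first + (nodes - nodes[0]) * scale
        kin = kin_unit / scale**2
        meta = {"scale": scale}
    else:
        points, kin = _cosine_dvr(n_points, first, last)
        meta = {}
    return DVRGrid(kind_norm, n_points, (first, last), points, kin, name=name, meta=meta)


def harmonic_dvr_natural(n_points: int, omega: float = 1.0, mass: float = 1.0,
                         center: float = 0.0, name: str = "") -> DVRGrid:
    """Harmonic DVR at its natural length scale 1/sqrt(m*omega) around ``center``.

    With this scaling the grid Hamiltonian kinetic/(2m) + diag(m omega^2 q^2/2)
    reproduces the oscillator levels (n + 1/2) omega for the low-lying states.
    """
    nodes, kin_unit = _hermite_unit_dvr(n_points)
    scale = 1.0 / math.sqrt(mass * omega)
    points = center + nodes * scale
    rng = (float(points[0]), float(points[-1])) if n_points > 1 else (center - scale, center + scale)
    return DVRGrid("harmonic", n_points, rng, points, kin_unit / scale**2,
                   name=name, meta={"scale": scale})


def primitive_grid_size(grids: list[DVRGrid]) -> int:
    """Total number of points of the direct-product primitive grid, prod(N_kappa)."""
    if not grids:
        raise ValueError("empty grid list")
    size = 1
    for g in grids:
        size *= int(g.n_points)
    return size


@dataclass(frozen=True)
class MultiGrid:
    """A primitive direct-product grid with its coarse and partial subgrids."""

    primitive: list[DVRGrid]
    stride: int
    coarse_index_sets: list[np.ndarray]

    @property
    def f(self) -> int:
        return len(self.primitive)

    def coarse_size(self) -> int:
        size = 1
        for s in self.coarse_index_sets:
            size *= len(s)
        return size

    def coarse_counts(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.coarse_index_sets)

    def partial_index_sets(self, dof: int) -> list[np.ndarray]:
        """Index sets of the partial grid of ``dof``: full along it, coarse elsewhere."""
        sets = [np.asarray(s) for s in self.coarse_index_sets]
        sets[dof] = np.arange(self.primitive[dof].n_points)
        return sets

    def partial_size(self, dof: int) -> int:
        size = self.primitive[dof].n_points
        for lam, s in enumerate(self.coarse_index_sets):
            if lam != dof:
                size *= len(s)
        return size


def make_multigrid(grids: list[DVRGrid], stride: int,
                   policy: str = "from_first") -> MultiGrid:
    """Build the coarse/partial multigrid structure for a stride.

    ``from_first`` keeps indices {0, k, 2k, ...}; ``from_first_plus_endpoint``
    additionally keeps the last index of each DOF when the progression misses
    it.  stride 1 reproduces the primitive grid exactly.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if policy not in ("from_first", "from_first_plus_endpoint"):
        raise ValueError(f"unknown coarse-grid policy {policy!r}")
    if grids and stride > min(g.n_points for g in grids):
        warnings.warn(
            f"stride {stride} exceeds the smallest grid size; some coarse sets "
            "collapse to a single point", stacklevel=2)
    sets = []
    for g in grids:
        idx = np.arange(0, g.n_points, stride)
        if policy == "from_first_plus_endpoint" and idx[-1] != g.n_points - 1:
            idx = np.append(idx, g.n_points - 1)
        sets.append(idx)
    return MultiGrid(list(grids), stride, sets)
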