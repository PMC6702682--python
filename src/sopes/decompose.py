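"""Exact POTFIT and bottom-up Multigrid POTFIT Tucker decompositions.

POTFIT builds the factor matrices of a full-grid potential tensor from the
eigenvectors ("natural potentials") of the per-DOF potential density
matrices

    rho^(kappa)_{kk'} = sum_{I^kappa} V[.., k, ..] V[.., k', ..]

where the sum runs over all DOFs except kappa.  At full rank the
decomposition is exact; truncating to the leading eigenvectors gives the
optimal L2 grid error, equal to the sum of the discarded eigenvalues.

Multigrid POTFIT (MGPF, bottom-up variant) never touches the full primitive
grid.  The backend is evaluated on a coarse direct-product grid (giving the
core tensor) and, for every DOF, on a partial grid that is full along that
DOF and coarse along the others.  From these, coarse-coarse density
matrices rho^(kappa) and mixed fine-coarse matrices rho^(kappa)' are
accumulated, and the fine-grid interpolation matrices

    gamma^(kappa) = rho^(kappa)' pinv(rho^(kappa))

extend the coarse core tensor to the full grid.  On the coarse points the
expansion is interpolatory (error 0 up to pseudo-inverse tolerance), and
for separable potentials it is exact everywhere at any stride.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from sopes.grids import MultiGrid
from sopes.sop_tensor import TuckerPotential, mode_product

__all__ = [
    "PotentialDensityMatrix",
    "MGPFResult",
    "BackendEvaluationError",
    "density_matrix",
    "potfit_exact",
    "mgpf_decompose",
    "rmse_on_grid",
]


class BackendEvaluationError(RuntimeError):
    """A backend failed at a grid point; carries the offending index."""

    def __init__(self, index, original):
        super().__init__(f"backend failed at grid index {index}: {original}")
        self.index = index
        self.original = original


@dataclass
class PotentialDensityMatrix:
    """Per-DOF Gram matrix of potential values summed over the other DOFs."""

    dof: int
    matrix: np.ndarray
    #: which grid the contraction index ran over ("full", "coarse")
    sum_index_set: str = "full"

    @property
    def is_mixed(self) -> bool:
        return self.matrix.shape[0] != self.matrix.shape[1]


def _unfold(values: np.ndarray, dof: int) -> np.ndarray:
    """Mode-``dof`` unfolding: shape (N_dof, prod of the rest)."""
    return np.moveaxis(values, dof, 0).reshape(values.shape[dof], -1)


def density_matrix(values: np.ndarray, dof: int,
                   sum_index_set: str = "full") -> PotentialDensityMatrix:
    """Potential density matrix of ``dof`` from a full- or partial-grid tensor."""
    values = np.asarray(values, dtype=float)
    if not 0 <= dof < values.ndim:
        raise IndexError(f"dof {dof} out of range for order-{values.ndim} tensor")
    mat = _unfold(values, dof)
    rho = mat @ mat.T
    return PotentialDensityMatrix(dof, 0.5 * (rho + rho.T), sum_index_set)


def mixed_density_matrix(partial_values: np.ndarray, coarse_values: np.ndarray,
                         dof: int) -> PotentialDensityMatrix:
    """Fine x coarse density matrix: first index on the primitive grid, second coarse.

    Both tensors must be coarse along every DOF but ``dof`` (same index sets,
    same ordering) so the contraction indices line up.
    """
    mp = _unfold(np.asarray(partial_values, float), dof)
    mc = _unfold(np.asarray(coarse_values, float), dof)
    if mp.shape[1] != mc.shape[1]:
        raise ValueError("partial and coarse tensors disagree on the contraction index")
    return PotentialDensityMatrix(dof, mp @ mc.T, "coarse")


def potfit_exact(values: np.ndarray, ranks: list[int] | None = None,
                 grids=None) -> TuckerPotential:
    """Exact (optionally truncated) POTFIT Tucker decomposition of a full tensor.

    Factors are the leading eigenvectors of each potential density matrix;
    at full ranks the reconstruction equals the input to machine precision.
    """
    values = np.asarray(values, dtype=float)
    if ranks is None:
        ranks = list(values.shape)
    factors, discarded = [], []
    for k in range(values.ndim):
        if ranks[k] > values.shape[k]:
            raise ValueError(f"rank {ranks[k]} exceeds grid size {values.shape[k]} on mode {k}")
        rho = density_matrix(values, k).matrix
        eigval, eigvec = np.linalg.eigh(rho)
        order = np.argsort(eigval)[::-1]
        factors.append(eigvec[:, order[: ranks[k]]])
        discarded.append(float(np.sum(np.clip(eigval[order[ranks[k]:]], 0.0, None))))
    core = values
    for k, v in enumerate(factors):
        core = mode_product(core, v.T, k)
    meta = {"builder": "potfit_exact", "ranks": list(ranks),
            "discarded_eigenvalue_sums": discarded}
    return TuckerPotential(core, factors, grids=grids, meta=meta)


@dataclass
class MGPFResult:
    """Outcome of a Multigrid POTFIT decomposition."""

    potential: TuckerPotential
    gammas: list[np.ndarray]
    n_calls: int
    rmse_report: dict = field(default_factory=dict)
    rho_condition: list[float] = field(default_factory=list)


def _eval_on_sets(backend, index_sets, cache) -> np.ndarray:
    """Evaluate the backend on a direct product of per-DOF index sets.

    Evaluation order is lexicographic and results are cached by full-grid
    index, so shared coarse points are computed once.
    """
    shape = tuple(len(s) for s in index_sets)
    out = np.empty(shape, dtype=float)
    for pos in itertools.product(*(range(n) for n in shape)):
        idx = tuple(int(index_sets[k][p]) for k, p in enumerate(pos))
        if idx not in cache:
            try:
                cache[idx] = float(backend(idx))
            except Exception as exc:  # surfaced with the offending index
                raise BackendEvaluationError(idx, exc) from exc
        out[pos] = cache[idx]
    return out


def _psd_pinv(rho: np.ndarray, rcond: float) -> tuple[np.ndarray, float]:
    """Eigenvalue-thresholded pseudo-inverse of a symmetric PSD matrix."""
    eigval, eigvec = np.linalg.eigh(rho)
    emax = float(np.max(np.abs(eigval))) if eigval.size else 0.0
    keep = eigval > rcond * emax
    inv = np.zeros_like(eigval)
    inv[keep] = 1.0 / eigval[keep]
    cond = emax / float(np.min(eigval[keep])) if np.any(keep) else np.inf
    return (eigvec * inv) @ eigvec.T, cond


def mgpf_decompose(backend, multigrid: MultiGrid, rcond: float = 1e-12,
                   cache: dict | None = None) -> MGPFResult:
    """Bottom-up Multigrid POTFIT decomposition of a backend on grid indices.

    Parameters
    ----------
    backend : callable
        Maps a full-primitive-grid index tuple to an energy.  Never called
        on the full primitive grid, only on coarse and partial points.
    multigrid : MultiGrid
        Coarse/partial structure from :func:`sopes.grids.make_multigrid`.
    rcond : float
        Relative eigenvalue threshold of the rho pseudo-inverse.
    """
    cache = {} if cache is None else cache
    f = multigrid.f
    coarse = _eval_on_sets(backend, multigrid.coarse_index_sets, cache)
    gammas, conds = [], []
    for k in range(f):
        partial = _eval_on_sets(backend, multigrid.partial_index_sets(k), cache)
        rho = density_matrix(coarse, k, "coarse").matrix
        rho_mixed = mixed_density_matrix(partial, coarse, k).matrix
        rho_inv, cond = _psd_pinv(rho, rcond)
        gammas.append(rho_mixed @ rho_inv)
        conds.append(cond)
    grids = multigrid.primitive
    meta = {"builder": "mgpf", "stride": multigrid.stride,
            "ranks": list(coarse.shape), "coarse_counts": list(multigrid.coarse_counts()),
            "energy_units": "cm-1"}
    pot = TuckerPotential(coarse, gammas, grids=grids, meta=meta)
    # error on the points already evaluated (coarse points are interpolated
    # exactly, partial points measure the genuine multigrid error)
    pts = np.array(sorted(cache.keys()), dtype=int)
    ref = np.array([cache[tuple(p)] for p in pts])
    fit = pot.evaluate_many(pts)
    resid = fit - ref
    report = {
        "points": "coarse+partial",
        "n": int(len(pts)),
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "max_abs_err": float(np.max(np.abs(resid))),
        "min_energy": float(np.min(fit)),
    }
    return MGPFResult(pot, gammas, n_calls=len(cache), rmse_report=report,
                      rho_condition=conds)


def rmse_on_grid(pot: TuckerPotential, backend, points="full",
                 rng: np.random.Generator | None = None) -> dict:
    """RMSE / max-error record of a Tucker potential against a backend.

    ``points`` is "full" (every primitive point; small grids only), an
    (n, f) integer array of indices, or "random(n, seed)".
    """
    shape = pot.shape
    if isinstance(points, str):
        if points == "full":
            idx = np.array(list(itertools.product(*(range(n) for n in shape))), dtype=int)
        elif points.startswith("random(") and points.endswith(")"):
            n_str, seed_str = points[7:-1].split(",")
            rng = np.random.default_rng(int(seed_str))
            idx = np.column_stack([rng.integers(0, nk, int(n_str)) for nk in shape])
        else:
            raise ValueError(f"unresolvable point spec {points!r}")
    else:
        idx = np.asarray(points, dtype=int)
        if idx.ndim != 2 or idx.shape[0] == 0:
            raise ValueError("empty or malformed point set")
    ref = np.array([float(backend(tuple(i))) for i in idx])
    fit = pot.evaluate_many(idx)
    resid = fit - ref
    return {
        "n": int(len(idx)),
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "max_abs_err": float(np.max(np.abs(resid))),
        "min_energy": float(np.min(fit)),
    }
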