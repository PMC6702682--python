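"""SRP objective functions, weighting, and global/local refitting protocol.

The reparametrization objective is a weighted mean-square error over
reference energies (and optionally harmonic frequencies of the stationary
points, recomputed at each trial parameter vector):

    chi0(zeta) = sum_i w_E(E_i^ref) [E_i^ref - E_i(zeta)]^2 / n
               + sum_j w_F(dF_j)    [F_j^ref - F_j(zeta)]^2 / m

with exponential step weights w(x) = 1 for x <= alpha, exp(beta (x - alpha))
otherwise (beta < 0 down-weights high energies / large frequency errors).
chi1 is the simpler single-term variant over the concatenated
energy||frequency vector divided by n + m.  The objective carries no square
root; reported RMSEs are the square root of the unweighted mean-square
energy residual over relative energies.

Optimization is derivative-free and bound-constrained: a multistart
global search with single-linkage clustering (seeded uniform starts, local
descents only from starts not lying in an already-explored basin, with a
shrinking critical radius) followed or continued by local quadratic-model
descents (scipy's Powell method).  Staged refits warm-start each stage from
the previous best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, minimize

from sopes.refset import ReferenceDataset
from sopes.stationary_vib import (
    NonConvergenceError,
    PointKind,
    WrongIndexError,
    refine_stationary,
)

__all__ = [
    "ObjectiveSpec",
    "FreqTerm",
    "FitLedger",
    "step_weight",
    "chi0",
    "chi1",
    "energy_rmse",
    "global_optimize",
    "local_optimize",
    "staged_fit",
    "cumulative_rmse",
]

#: finite penalty returned when a trial zeta breaks the backend or the
#: stationary-point refinement -- keeps derivative-free searches alive
CHI_PENALTY = 1.0e6


def step_weight(x, alpha: float, beta: float):
    """Exponential step weight: 1 for x <= alpha, exp(beta (x - alpha)) beyond."""
    x = np.asarray(x, dtype=float)
    out = np.where(x <= alpha, 1.0, np.exp(beta * (np.minimum(x, 1e300) - alpha)))
    return out if out.ndim else float(out)


@dataclass
class FreqTerm:
    """One stationary point whose harmonic frequencies enter the objective."""

    guess: np.ndarray
    kind: PointKind
    reference_frequencies: np.ndarray
    masses: np.ndarray | None = None


@dataclass
class ObjectiveSpec:
    """Everything a chi evaluation needs."""

    dataset: ReferenceDataset          # entries carry reference relative energies
    backend: object                    # SurfaceBackend
    reference_geometry: np.ndarray     # zeta-dependent energy zero (global minimum)
    form: str = "chi1"
    alpha_E: float = 4000.0            # cm^-1, roughly the barrier height
    beta_E: float = -1.0e-3
    alpha_F: float = 100.0             # cm^-1
    beta_F: float = -1.0e-2
    freq_terms: list[FreqTerm] = field(default_factory=list)
    penalty: float = CHI_PENALTY
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.dataset) == 0:
            raise ValueError("objective needs at least one energy entry")


def _model_energies(spec: ObjectiveSpec, zeta) -> np.ndarray:
    backend = spec.backend
    geoms = spec.dataset.geometries()
    e0 = backend.energy(spec.reference_geometry, zeta)
    if hasattr(backend, "energy_many"):
        return backend.energy_many(geoms, zeta) - e0
    return np.array([backend.energy(g, zeta) for g in geoms]) - e0


def _freq_residuals(spec: ObjectiveSpec, zeta):
    """(reference, model) frequency arrays, modes compared after ascending sort."""
    ref, mod = [], []
    for term in spec.freq_terms:
        sp = refine_stationary(spec.backend, zeta, term.guess, term.kind,
                               masses=term.masses)
        f_ref = np.sort(np.asarray(term.reference_frequencies, float))
        f_mod = np.sort(sp.frequencies)[: f_ref.size]
        ref.append(f_ref)
        mod.append(f_mod)
    if not ref:
        return np.array([]), np.array([])
    return np.concatenate(ref), np.concatenate(mod)


def chi0(zeta, spec: ObjectiveSpec) -> float:
    """Two-term weighted mean-square objective (energies + frequencies)."""
    try:
        e_ref = spec.dataset.energies()
        e_mod = _model_energies(spec, zeta)
        term = float(np.sum(step_weight(e_ref, spec.alpha_E, spec.beta_E)
                            * (e_ref - e_mod) ** 2) / e_ref.size)
        f_ref, f_mod = _freq_residuals(spec, zeta)
        if f_ref.size:
            df = f_ref - f_mod
            term += float(np.sum(step_weight(np.abs(df), spec.alpha_F, spec.beta_F)
                                 * df**2) / f_ref.size)
        return term if np.isfinite(term) else spec.penalty
    except (NonConvergenceError, WrongIndexError, FloatingPointError,
            np.linalg.LinAlgError) as exc:
        spec.flags.append(str(exc))
        return spec.penalty


def chi1(zeta, spec: ObjectiveSpec) -> float:
    """Single-term variant over the concatenated energy||frequency vector."""
    try:
        e_ref = spec.dataset.energies()
        e_mod = _model_energies(spec, zeta)
        f_ref, f_mod = _freq_residuals(spec, zeta)
        g_ref = np.concatenate([e_ref, f_ref])
        g_mod = np.concatenate([e_mod, f_mod])
        w = np.concatenate([step_weight(e_ref, spec.alpha_E, spec.beta_E),
                            step_weight(np.abs(f_ref - f_mod), spec.alpha_F,
                                        spec.beta_F)])
        val = float(np.sum(w * (g_ref - g_mod) ** 2) / g_ref.size)
        return val if np.isfinite(val) else spec.penalty
    except (NonConvergenceError, WrongIndexError, FloatingPointError,
            np.linalg.LinAlgError) as exc:
        spec.flags.append(str(exc))
        return spec.penalty


def make_objective(spec: ObjectiveSpec):
    fun = {"chi0": chi0, "chi1": chi1}[spec.form]
    return lambda zeta: fun(zeta, spec)


def energy_rmse(zeta, spec: ObjectiveSpec) -> float:
    """Unweighted RMSE of relative energies (the reported fit quality)."""
    resid = spec.dataset.energies() - _model_energies(spec, zeta)
    return float(np.sqrt(np.mean(resid**2)))


class _Counter:
    def __init__(self, fun):
        self.fun, self.n = fun, 0

    def __call__(self, x):
        self.n += 1
        return self.fun(x)


def local_optimize(objective, bounds: np.ndarray, zeta_start, max_evals: int = 2000
                   ) -> tuple[np.ndarray, float]:
    """Bound-constrained derivative-free local descent (quadratic-model Powell).

    Never returns a point worse than the start.
    """
    b = np.asarray(bounds, float)
    x0 = np.clip(np.asarray(zeta_start, float), b[:, 0], b[:, 1])
    counter = _Counter(objective)
    chi_start = counter(x0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(counter, x0, method="Powell",
                       bounds=Bounds(b[:, 0], b[:, 1]),
                       options={"maxfev": max_evals, "xtol": 1e-10, "ftol": 1e-12})
    if res.fun <= chi_start:
        return np.clip(res.x, b[:, 0], b[:, 1]), float(res.fun)
    return x0, float(chi_start)


def global_optimize(objective, bounds: np.ndarray, n_starts: int = 40,
                    max_evals: int = 20000, seed: int = 0, sigma: float = 1.0
                    ) -> tuple[np.ndarray, float, dict]:
    """Multistart global search with single-linkage clustering.

    Seeded uniform starts are ranked by objective value; a local descent is
    launched from a start only if no already-descended start lies within the
    critical radius r_k = sigma (log k / k)^(1/D) in the unit-normalized
    box (duplicate-basin suppression).  The evaluation budget covers the
    start scan and all descents.
    """
    if max_evals < n_starts:
        raise ValueError("max_evals must cover at least the start evaluations")
    b = np.asarray(bounds, float)
    width = b[:, 1] - b[:, 0]
    d = b.shape[0]
    rng = np.random.default_rng(seed)
    starts = rng.uniform(b[:, 0], b[:, 1], size=(n_starts, d))
    counter = _Counter(objective)
    chis = np.array([counter(x) for x in starts])
    order = np.argsort(chis)
    descended: list[np.ndarray] = []
    results = []
    budget = max_evals - counter.n
    per_descent = max(100, budget // max(1, n_starts // 4))
    report = {"n_starts": n_starts, "descents": 0, "skipped_clustered": 0,
              "failures": 0}
    for rank, idx in enumerate(order, start=1):
        if counter.n >= max_evals:
            break
        x = starts[idx]
        r = sigma * (np.log(rank + 1) / (rank + 1)) ** (1.0 / d)
        if any(np.linalg.norm((x - y) / width) < r for y in descended):
            report["skipped_clustered"] += 1
            continue
        descended.append(x)
        budget_now = min(per_descent, max_evals - counter.n)
        xb, fb = local_optimize(counter, b, x, max_evals=budget_now)
        results.append((xb, fb))
        report["descents"] += 1
    if not results:
        # all starts clustered away or budget exhausted: descend from the best start
        xb, fb = local_optimize(counter, b, starts[order[0]],
                                max_evals=max(100, max_evals - counter.n))
        results.append((xb, fb))
        report["descents"] += 1
    best = min(results, key=lambda t: t[1])
    report["n_evals"] = counter.n
    report["minima_found"] = [float(f) for _, f in results]
    return best[0], float(best[1]), report


@dataclass
class FitLedger:
    """Per-stage record of a staged refit."""

    records: list = field(default_factory=list)

    def append(self, **kwargs):
        self.records.append(kwargs)

    @property
    def best_zeta(self):
        return np.asarray(self.records[-1]["best_zeta"], float)

    def to_json_dict(self) -> dict:
        return {"stages": self.records}


def staged_fit(stages: list[ObjectiveSpec], bounds: np.ndarray, zeta_start,
               n_starts: int = 30, global_evals: int = 10000,
               local_evals: int = 2000, seed: int = 0) -> FitLedger:
    """Staged refitting protocol: global+local on stage 1, warm-started local after.

    ``stages`` are ready objective specifications (typically nested datasets
    of increasing size); each later stage starts from the previous best
    parameter vector.
    """
    if not stages:
        raise ValueError("need at least one stage")
    ledger = FitLedger()
    zeta = np.asarray(zeta_start, float)
    for i, spec in enumerate(stages):
        objective = make_objective(spec)
        try:
            if i == 0:
                zg, chi_g, report = global_optimize(
                    objective, bounds, n_starts=n_starts, max_evals=global_evals,
                    seed=seed)
                # keep the warm start in play: the perturbed-start basin may
                # beat the best sampled cluster
                z0 = zg if chi_g <= objective(zeta) else zeta
                zeta, chi, optimizer = *local_optimize(objective, bounds, z0,
                                                       local_evals), "global+local"
            else:
                report = None
                zeta, chi = local_optimize(objective, bounds, zeta, local_evals)
                optimizer = "local"
        except Exception as exc:
            ledger.append(stage=f"stage{i + 1}", error=str(exc))
            raise
        start = np.asarray(zeta_start, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(start != 0, 100.0 * (zeta - start) / start, 0.0)
        ledger.append(
            stage=f"stage{i + 1}",
            n_points=len(spec.dataset),
            optimizer=optimizer,
            best_chi=float(chi),
            rmse=energy_rmse(zeta, spec),
            best_zeta=[float(z) for z in zeta],
            percent_deviation_from_start=[float(p) for p in pct],
            cluster_report=report,
        )
    return ledger


def cumulative_rmse(dataset: ReferenceDataset, backend, zeta,
                    energy_cutoffs, reference_geometry) -> list[dict]:
    """RMSE over entries with reference energy <= cutoff, per ascending cutoff.

    Empty bins are omitted and flagged.
    """
    cutoffs = np.asarray(energy_cutoffs, float)
    if np.any(np.diff(cutoffs) < 0):
        raise ValueError("cutoffs must be ascending")
    e_ref = dataset.energies()
    e0 = backend.energy(reference_geometry, zeta)
    geoms = dataset.geometries()
    if hasattr(backend, "energy_many"):
        e_mod = backend.energy_many(geoms, zeta) - e0
    else:
        e_mod = np.array([backend.energy(g, zeta) for g in geoms]) - e0
    resid2 = (e_ref - e_mod) ** 2
    curve = []
    for c in cutoffs:
        mask = e_ref <= c
        if not np.any(mask):
            curve.append({"cutoff": float(c), "rmse": None, "n": 0, "flag": "empty bin"})
            continue
        curve.append({"cutoff": float(c),
                      "rmse": float(np.sqrt(np.mean(resid2[mask]))),
                      "n": int(np.sum(mask))})
    return curve
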