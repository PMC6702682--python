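"""Staged reference datasets: displacement grids, random points, LIIC paths.

The fitting sets mirror an n-body expansion around pivot stationary points:
1D cuts (one coordinate displaced, the rest at the pivot), 2D product grids
over coordinate pairs, full-dimensional random points, piecewise linear
interpolation in internal coordinates (LIIC) between stationary points as a
reaction-path surrogate, and clouds of distorted geometries around the
path.  Stages are concatenations of these classes, deduplicated by geometry
hash, and carry a ledger of their class composition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sopes.stationary_vib import StationaryPoint

__all__ = [
    "RefEntry",
    "ReferenceDataset",
    "LIICPath",
    "CLASS_TAGS",
    "grid_displacements",
    "random_fD",
    "liic",
    "liic_cloud",
    "filter_by_energy",
    "assemble_stage",
]

CLASS_TAGS = ("core", "1D", "2D", "rnd(fD)", "LIIC", "rnd(LIIC)", "asymp")


@dataclass
class RefEntry:
    geometry: np.ndarray
    energy: float | None = None
    frequencies: np.ndarray | None = None
    tag: str = "core"
    stage: str = ""

    def __post_init__(self):
        if self.tag not in CLASS_TAGS:
            raise ValueError(f"unknown class tag {self.tag!r}; allowed {CLASS_TAGS}")


def _geom_key(geometry: np.ndarray, decimals: int = 10) -> bytes:
    return np.round(np.asarray(geometry, float), decimals).tobytes()


@dataclass
class ReferenceDataset:
    """An ordered collection of reference geometries with provenance."""

    entries: list[RefEntry] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def geometries(self) -> np.ndarray:
        return np.array([e.geometry for e in self.entries])

    def energies(self) -> np.ndarray:
        return np.array([np.nan if e.energy is None else e.energy for e in self.entries])

    def with_energies(self, backend, zeta=None, reference_energy: float = 0.0
                      ) -> "ReferenceDataset":
        """Evaluate a backend on every geometry, storing relative energies."""
        out = []
        for e in self.entries:
            out.append(RefEntry(e.geometry, backend.energy(e.geometry, zeta)
                                - reference_energy, e.frequencies, e.tag, e.stage))
        return ReferenceDataset(out, dict(self.provenance))

    def concat(self, other: "ReferenceDataset") -> "ReferenceDataset":
        return ReferenceDataset(list(self.entries) + list(other.entries),
                                {**self.provenance, **other.provenance})

    def composition(self) -> dict:
        comp: dict = {}
        for e in self.entries:
            comp[e.tag] = comp.get(e.tag, 0) + 1
        return comp

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"tag": e.tag, "stage": e.stage, "energy": e.energy}
            row.update({f"q{i}": x for i, x in enumerate(e.geometry)})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "ReferenceDataset":
        df = pd.read_csv(path)
        qcols = sorted((c for c in df.columns if c.startswith("q")),
                       key=lambda c: int(c[1:]))
        entries = [RefEntry(row[qcols].to_numpy(float),
                            None if pd.isna(row["energy"]) else float(row["energy"]),
                            None, row["tag"], str(row["stage"]))
                   for _, row in df.iterrows()]
        return ReferenceDataset(entries)


def grid_displacements(pivot: StationaryPoint, order: int, dofs: list[int],
                       deltas, n_per_dof: int, tag: str | None = None,
                       bounds=None) -> ReferenceDataset:
    """1D cuts or 2D product grids of displacements around a pivot geometry.

    1D: ``n_per_dof`` symmetric displacements along each selected DOF, the
    others fixed at the pivot (the pivot itself is excluded).  2D: product
    grids over every DOF pair.  Displacements escaping ``bounds`` are
    clipped and flagged in the provenance.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    deltas = np.broadcast_to(np.asarray(deltas, float), (len(pivot.geometry),))
    if np.any(deltas[list(dofs)] <= 0):
        raise ValueError("deltas must be positive")
    tag = tag or ("1D" if order == 1 else "2D")
    g0 = np.asarray(pivot.geometry, float)
    entries, clipped = [], 0

    def offsets(i):
        if n_per_dof == 0:
            return np.array([])
        # n_per_dof symmetric nonzero displacements up to +-deltas[i]
        half = (n_per_dof + 1) // 2
        pos = np.linspace(deltas[i] / half, deltas[i], half)
        off = np.concatenate([-pos[::-1], pos])
        if n_per_dof % 2:
            off = off[:-1]
        return off[:n_per_dof]

    if order == 1:
        for i in dofs:
            for dx in offsets(i):
                g = g0.copy()
                g[i] += dx
                entries.append((g,))
    else:
        for i, j in itertools.combinations(dofs, 2):
            for dx, dy in itertools.product(offsets(i), offsets(j)):
                g = g0.copy()
                g[i] += dx
                g[j] += dy
                entries.append((g,))
    out = []
    for (g,) in entries:
        if bounds is not None:
            b = np.asarray(bounds, float)
            gc = np.clip(g, b[:, 0], b[:, 1])
            if not np.array_equal(gc, g):
                clipped += 1
                g = gc
        out.append(RefEntry(g, tag=tag))
    prov = {"pivot": g0.tolist(), "order": order, "n_per_dof": n_per_dof,
            "clipped": clipped}
    return ReferenceDataset(out, {"displacements": prov})


def random_fD(bounds, n: int, seed: int, tag: str = "rnd(fD)") -> ReferenceDataset:
    """Seeded uniform random geometries in a box of per-DOF bounds."""
    if n < 0:
        raise ValueError("n must be >= 0")
    b = np.asarray(bounds, float)
    rng = np.random.default_rng(seed)
    geoms = rng.uniform(b[:, 0], b[:, 1], size=(n, b.shape[0]))
    return ReferenceDataset([RefEntry(g, tag=tag) for g in geoms],
                            {"random": {"n": n, "seed": seed}})


@dataclass
class LIICPath:
    endpoints: tuple
    points: np.ndarray  # (n, f)
    X: np.ndarray       # interpolation ordinate in [0, 1]


def liic(init: StationaryPoint, fin: StationaryPoint, n_points: int = 50,
         periodic=None) -> LIICPath:
    """Piecewise linear interpolation in internal coordinates.

    Periodic DOFs (period 2 pi) are interpolated along the shorter arc, so a
    path from 350 deg to 10 deg passes through 0 deg.
    """
    a = np.asarray(init.geometry, float)
    b = np.asarray(fin.geometry, float)
    if a.shape != b.shape:
        raise ValueError("endpoint dimension mismatch")
    delta = b - a
    if periodic is not None:
        per = np.asarray(periodic, bool)
        delta[per] = (delta[per] + np.pi) % (2 * np.pi) - np.pi
    x = np.linspace(0.0, 1.0, n_points)
    pts = a[None, :] + x[:, None] * delta[None, :]
    return LIICPath((init, fin), pts, x)


def liic_cloud(path: LIICPath, modes_init: np.ndarray, modes_fin: np.ndarray,
               n_per_point: int, factor_scale: float, seed: int,
               exclude_mode: int | None = None, tag: str = "rnd(LIIC)"
               ) -> ReferenceDataset:
    """Cloud of distorted geometries around an interpolated reaction path.

    At path point i the distortion directions are the blend
    (1 - X_i) * modes_init + X_i * modes_fin (with the excluded mode, e.g.
    the torsion that plays the role of the reaction coordinate, removed from
    both), and each cloud geometry adds f_j * direction_j with f_j drawn
    uniformly from (-factor_scale, +factor_scale).
    """
    mi = np.asarray(modes_init, float).copy()
    mf = np.asarray(modes_fin, float).copy()
    if exclude_mode is not None:
        if not 0 <= exclude_mode < mi.shape[1]:
            raise ValueError(f"excluded mode index {exclude_mode} invalid")
        keep = [j for j in range(mi.shape[1]) if j != exclude_mode]
        mi, mf = mi[:, keep], mf[:, keep]
    rng = np.random.default_rng(seed)
    entries = []
    for i, (x, g0) in enumerate(zip(path.X, path.points)):
        dq = (1.0 - x) * mi + x * mf  # (f, n_modes)
        for _ in range(n_per_point):
            fac = rng.uniform(-factor_scale, factor_scale, dq.shape[1])
            entries.append(RefEntry(g0 + dq @ fac, tag=tag))
    prov = {"cloud": {"n_per_point": n_per_point, "factor_scale": factor_scale,
                      "seed": seed, "exclude_mode": exclude_mode}}
    return ReferenceDataset(entries, prov)


def path_dataset(path: LIICPath, tag: str = "LIIC") -> ReferenceDataset:
    return ReferenceDataset([RefEntry(g, tag=tag) for g in path.points])


def filter_by_energy(dataset: ReferenceDataset, backend_or_values, cutoff: float,
                     zeta=None, reference_energy: float = 0.0) -> ReferenceDataset:
    """Keep entries with relative energy <= cutoff (inclusive).

    ``backend_or_values`` is a backend (energies computed on the fly), an
    array of energies aligned with the dataset, or None (use stored
    energies).
    """
    if backend_or_values is None:
        energies = dataset.energies()
    elif hasattr(backend_or_values, "energy"):
        energies = np.array([backend_or_values.energy(e.geometry, zeta)
                             - reference_energy for e in dataset])
    else:
        energies = np.asarray(backend_or_values, float)
    keep = energies <= cutoff
    removed = int(np.sum(~keep))
    if removed == len(dataset) and len(dataset) > 0:
        warnings.warn("energy filter removed every entry", stacklevel=2)
    entries = [RefEntry(e.geometry, float(en), e.frequencies, e.tag, e.stage)
               for e, en, k in zip(dataset, energies, keep) if k]
    prov = dict(dataset.provenance)
    prov["energy_filter"] = {"cutoff": float(cutoff), "removed": removed}
    return ReferenceDataset(entries, prov)


def assemble_stage(stage_id: str, components: list[ReferenceDataset],
                   existing_ids: set | None = None) -> tuple[ReferenceDataset, dict]:
    """Concatenate component datasets into a stage, deduplicating geometries.

    Returns the stage dataset and a ledger row (stage id, class composition
    string, counts per class, total).
    """
    if existing_ids is not None and stage_id in existing_ids:
        raise ValueError(f"clashing stage id {stage_id!r}")
    seen, entries = set(), []
    for comp in components:
        for e in comp:
            key = _geom_key(e.geometry)
            if key in seen:
                continue
            seen.add(key)
            entries.append(RefEntry(e.geometry, e.energy, e.frequencies, e.tag, stage_id))
    ds = ReferenceDataset(entries, {"stage": stage_id})
    comp_counts = ds.composition()
    order = [t for t in CLASS_TAGS if t in comp_counts]
    ledger = {"stage": stage_id,
              "class_of_points": " + ".join(order),
              "composition": comp_counts,
              "n_points": len(ds)}
    assert sum(comp_counts.values()) == len(ds)
    return ds, ledger
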