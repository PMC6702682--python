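"""Parametrized-surface contract, the analytic toy family and an external adapter.

The toy family is a chain of coupled harmonic coordinates attached to one
periodic torsion, a minimal surrogate for a cis/trans isomerizing molecule:

    V(q, phi) = sum_k a_k (q_k - r_k(phi))^2 / 2
              + sum_{k<l} b_kl (q_k - r_k(phi)) (q_l - r_l(phi))
              + c1 (1 - cos phi) + c2 (1 - cos 2phi),
    r_k(phi) = q0_k + d_k cos phi

With c1 small and c2 > 0 the torsional profile has two inequivalent wells
(phi = 0 and phi = pi) separated by a barrier, the chain equilibria shift
with the torsion (d_k) and the bilinear couplings (b_kl) make the tensor
non-separable.  Energies are in cm^-1 in the package's natural unit system
(see :mod:`sopes.units`): with unit masses the decoupled harmonic
frequencies are sqrt(a_k) cm^-1, so curvatures around 1e6 cm^-1 give
molecule-like stretch/bend frequencies of ~1000 cm^-1.

The external adapter turns a declarative program spec (command, input
template, output regex) into the same backend contract, dispatching one
process per geometry and caching by (geometry, parameter) hash.
"""

from __future__ import annotations

import hashlib
import re
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ParamVector",
    "SurfaceBackend",
    "ToyTorsionSurface",
    "toy_reference",
    "perturb_params",
    "external_adapter",
    "ExternalBackend",
    "ExternalBackendError",
    "read_xyz",
    "write_xyz",
]


@dataclass
class ParamVector:
    """Named surface parameters zeta with box bounds."""

    names: list[str]
    values: np.ndarray
    bounds: np.ndarray  # (D, 2)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bounds = np.asarray(self.bounds, dtype=float)
        if not (len(self.names) == self.values.size == self.bounds.shape[0]):
            raise ValueError("names, values and bounds disagree in length")
        if np.any(self.values < self.bounds[:, 0] - 1e-12) or np.any(
                self.values > self.bounds[:, 1] + 1e-12):
            raise ValueError("parameter values outside declared bounds")

    @property
    def dim(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray) -> "ParamVector":
        return ParamVector(list(self.names), np.asarray(values, float), self.bounds.copy())

    def as_dict(self) -> dict:
        return dict(zip(self.names, map(float, self.values)))


class SurfaceBackend:
    """Contract for a parametrized potential-energy backend.

    Subclasses provide deterministic ``energy(geometry, zeta)`` (zeta=None
    means the backend's own parameters) and metadata; gradient/hessian are
    optional.  Periodic DOFs are evaluated modulo their period.
    """

    dof_count: int
    coord_names: list[str]
    periodic: np.ndarray  # bool per DOF

    def energy(self, geometry: np.ndarray, zeta: np.ndarray | None = None) -> float:
        raise NotImplementedError

    def energy_many(self, geometries: np.ndarray, zeta=None) -> np.ndarray:
        """Energies at an (n, f) array of geometries (loop fallback)."""
        return np.array([self.energy(g, zeta) for g in np.asarray(geometries, float)])

    def gradient(self, geometry, zeta=None) -> np.ndarray:
        raise NotImplementedError

    def hessian(self, geometry, zeta=None) -> np.ndarray:
        raise NotImplementedError

def _pair_index(f_chain: int):
    return [(k, l) for k in range(f_chain) for l in range(k + 1, f_chain)]


class ToyTorsionSurface(SurfaceBackend):
    """Coupled-chain + torsion analytic surface (see module docstring).

    Coordinates: f-1 chain coordinates followed by one periodic torsion phi.
    Parameters (in order): a_1..a_{f-1}, d_1..d_{f-1}, b_kl (k<l),
    c1, c2, q0_1..q0_{f-1}.
    """

    def __init__(self, params: ParamVector, f: int, masses: np.ndarray | None = None):
        nc = f - 1
        expected = 2 * nc + nc * (nc - 1) // 2 + 2 + nc
        if params.dim != expected:
            raise ValueError(f"expected {expected} parameters for f={f}, got {params.dim}")
        self.params = params
        self.dof_count = f
        self.coord_names = [f"q{k + 1}" for k in range(nc)] + ["phi"]
        self.periodic = np.array([False] * nc + [True])
        self.masses = np.ones(f) if masses is None else np.asarray(masses, float)
        self._nc = nc
        self._pairs = _pair_index(nc)

    # parameter unpacking -------------------------------------------------
    def _unpack(self, zeta):
        z = self.params.values if zeta is None else np.asarray(zeta, float)
        nc, npair = self._nc, len(self._pairs)
        a = z[:nc]
        d = z[nc:2 * nc]
        b = z[2 * nc:2 * nc + npair]
        c1, c2 = z[2 * nc + npair], z[2 * nc + npair + 1]
        q0 = z[2 * nc + npair + 2:]
        bmat = np.zeros((nc, nc))
        for (k, l), bv in zip(self._pairs, b):
            bmat[k, l] = bmat[l, k] = bv
        return a, d, bmat, c1, c2, q0

    @staticmethod
    def param_names(f: int) -> list[str]:
        nc = f - 1
        names = [f"a{k + 1}" for k in range(nc)]
        names += [f"d{k + 1}" for k in range(nc)]
        names += [f"b{k + 1}{l + 1}" for k, l in _pair_index(nc)]
        names += ["c1", "c2"]
        names += [f"q0_{k + 1}" for k in range(nc)]
        return names

    # energetics ----------------------------------------------------------
    def energy(self, geometry, zeta=None) -> float:
        g = np.asarray(geometry, dtype=float)
        a, d, bmat, c1, c2, q0 = self._unpack(zeta)
        phi = g[-1]
        delta = g[:-1] - (q0 + d * np.cos(phi))
        chain = 0.5 * np.sum(a * delta**2) + 0.5 * delta @ bmat @ delta
        tors = c1 * (1.0 - np.cos(phi)) + c2 * (1.0 - np.cos(2.0 * phi))
        return float(chain + tors)

    def energy_many(self, geometries, zeta=None) -> np.ndarray:
        g = np.asarray(geometries, dtype=float)
        a, d, bmat, c1, c2, q0 = self._unpack(zeta)
        phi = g[:, -1]
        delta = g[:, :-1] - (q0[None, :] + np.outer(np.cos(phi), d))
        chain = 0.5 * np.sum(a * delta**2, axis=1) + 0.5 * np.einsum(
            "ni,ij,nj->n", delta, bmat, delta)
        tors = c1 * (1.0 - np.cos(phi)) + c2 * (1.0 - np.cos(2.0 * phi))
        return chain + tors

    def gradient(self, geometry, zeta=None) -> np.ndarray:
        g = np.asarray(geometry, dtype=float)
        a, d, bmat, c1, c2, q0 = self._unpack(zeta)
        phi = g[-1]
        delta = g[:-1] - (q0 + d * np.cos(phi))
        gchain = a * delta + bmat @ delta
        dphi = float(np.sum(gchain * d) * np.sin(phi)
                     + c1 * np.sin(phi) + 2.0 * c2 * np.sin(2.0 * phi))
        return np.append(gchain, dphi)

    def hessian(self, geometry, zeta=None) -> np.ndarray:
        g = np.asarray(geometry, dtype=float)
        a, d, bmat, c1, c2, q0 = self._unpack(zeta)
        f = self.dof_count
        phi = g[-1]
        s, c = np.sin(phi), np.cos(phi)
        delta = g[:-1] - (q0 + d * c)
        A = np.diag(a) + bmat
        H = np.zeros((f, f))
        H[:-1, :-1] = A
        H[:-1, -1] = H[-1, :-1] = (A @ d) * s
        gchain = A @ delta
        H[-1, -1] = float((d @ A @ d) * s**2 + np.sum(gchain * d) * c
                          + c1 * c + 4.0 * c2 * np.cos(2.0 * phi))
        return H

    # geometry helpers ----------------------------------------------------
    def relaxed_chain(self, phi: float, zeta=None) -> np.ndarray:
        """Geometry with the chain at its conditional minimum for a torsion angle."""
        a, d, _, _, _, q0 = self._unpack(zeta)
        return np.append(q0 + d * np.cos(phi), phi)

    def minima_guesses(self, zeta=None) -> list[np.ndarray]:
        return [self.relaxed_chain(0.0, zeta), self.relaxed_chain(np.pi, zeta)]

    def ts_guess(self, zeta=None) -> np.ndarray:
        return self.relaxed_chain(np.pi / 2.0, zeta)

    def coordinate_bounds(self, zeta=None, width: float = 0.6) -> np.ndarray:
        """Sensible box for sampling: chain within +-width of q0, full torsion."""
        _, _, _, _, _, q0 = self._unpack(zeta)
        lo = np.append(q0 - width, 0.0)
        hi = np.append(q0 + width, 2.0 * np.pi)
        return np.column_stack([lo, hi])


class MorseTorsionSurface(ToyTorsionSurface):
    """Anharmonic member of the toy family: Morse wells along the chain.

    Each chain displacement enters through the Morse variable
    y_k = (1 - exp(-alpha_k delta_k)) / alpha_k (y -> delta as alpha -> 0),
    so wells soften on one side and stiffen on the other while the
    curvatures at the minima stay a_k.  Because exp(-alpha delta(phi))
    carries a factor exp(alpha d cos phi), the chain-torsion coupling has an
    infinite Fourier expansion: unlike the harmonic member, this surface has
    no finite-rank Tucker form and is the stress case for grid
    decompositions.  ``alphas`` are inverse-length anharmonicities (one per
    chain coordinate), not part of the fitted parameter vector.
    """

    def __init__(self, params: ParamVector, f: int, alphas, masses=None):
        super().__init__(params, f, masses=masses)
        self.alphas = np.broadcast_to(np.asarray(alphas, float), (f - 1,)).copy()

    def _morse_y(self, delta):
        return (1.0 - np.exp(-self.alphas * delta)) / self.alphas

    def energy(self, geometry, zeta=None) -> float:
        g = np.asarray(geometry, dtype=float)
        a, d, bmat, c1, c2, q0 = self._unpack(zeta)
        phi = g[-1]
        y = self._morse_y(g[:-1] - (q0 + d * np.cos(phi)))
        chain = 0.5 * np.sum(a * y**2) + 0.5 * y @ bmat @ y
        return float(chain + c1 * (1.0 - np.cos(phi)) + c2 * (1.0 - np.cos(2.0 * phi)))

    def energy_many(self, geometries, zeta=None) -> np.ndarray:
        g = np.asarray(geometries, dtype=float)
        a, d, bmat, c1, c2, q0 = self._unpack(zeta)
        phi = g[:, -1]
        delta = g[:, :-1] - (q0[None, :] + np.outer(np.cos(phi), d))
        y = (1.0 - np.exp(-self.alphas[None, :] * delta)) / self.alphas[None, :]
        chain = 0.5 * np.sum(a * y**2, axis=1) + 0.5 * np.einsum(
            "ni,ij,nj->n", y, bmat, y)
        return chain + c1 * (1.0 - np.cos(phi)) + c2 * (1.0 - np.cos(2.0 * phi))

    def gradient(self, geometry, zeta=None) -> np.ndarray:
        g = np.asarray(geometry, dtype=float)
        a, d, bmat, c1, c2, q0 = self._unpack(zeta)
        phi = g[-1]
        delta = g[:-1] - (q0 + d * np.cos(phi))
        y = self._morse_y(delta)
        dyddelta = np.exp(-self.alphas * delta)
        gy = a * y + bmat @ y            # dV/dy
        gchain = gy * dyddelta           # dV/ddelta
        dphi = float(np.sum(gchain * d) * np.sin(phi)
                     + c1 * np.sin(phi) + 2.0 * c2 * np.sin(2.0 * phi))
        return np.append(gchain, dphi)

    def hessian(self, geometry, zeta=None) -> np.ndarray:
        raise NotImplementedError  # numerical Hessian applies


def toy_reference(seed: int = 0, f: int = 3) -> tuple[ToyTorsionSurface, dict]:
    """A deterministic reference instance of the toy family.

    Parameter magnitudes emulate a small isomerizing molecule: chain
    curvatures give harmonic frequencies of 800-3200 cm^-1, the torsional
    barrier (~2 c2) is a few thousand cm^-1, the cis/trans asymmetry (2 c1)
    a few hundred, equilibrium shifts along the torsion of a few percent and
    bilinear couplings of a few percent of the diagonal curvatures.
    """
    rng = np.random.default_rng(seed)
    nc = f - 1
    freqs = rng.uniform(800.0, 3200.0, nc)          # cm^-1
    a = freqs**2                                    # unit masses: omega = sqrt(a)
    d = rng.uniform(0.02, 0.08, nc)
    b = np.array([rng.uniform(0.02, 0.06) * np.sqrt(a[k] * a[l])
                  for k, l in _pair_index(nc)])
    c1, c2 = 150.0, 2000.0
    q0 = rng.uniform(1.5, 2.5, nc)
    values = np.concatenate([a, d, b, [c1, c2], q0])
    bounds = np.column_stack([
        np.minimum(values * 0.5, values * 1.5),
        np.maximum(values * 0.5, values * 1.5),
    ])
    pv = ParamVector(ToyTorsionSurface.param_names(f), values, bounds)
    surface = ToyTorsionSurface(pv, f)
    meta = {"seed": int(seed), "f": int(f), "zeta_star": pv.as_dict(),
            "barrier_cm1": 2.0 * c2, "asymmetry_cm1": 2.0 * c1}
    return surface, meta


def toy_reference_morse(seed: int = 0, f: int = 3, alpha: float = 3.0,
                        d_scale: float = 4.0) -> tuple[MorseTorsionSurface, dict]:
    """Morse-well (anharmonic, full-Tucker-rank) reference toy instance.

    Compared to the harmonic member, the torsion-induced equilibrium shifts
    are amplified (``d_scale``, giving shifts of 0.1-0.3 as in a strongly
    isomerizing bond) so the chain-torsion coupling exp(alpha d cos phi)
    carries appreciable high-order Fourier content -- the regime where a
    coarse-grid decomposition has genuine, measurable error.
    """
    harmonic, meta = toy_reference(seed, f)
    pv = harmonic.params
    values = pv.values.copy()
    nc = f - 1
    values[nc:2 * nc] *= d_scale
    bounds = pv.bounds.copy()
    bounds[nc:2 * nc] *= d_scale
    pv = ParamVector(list(pv.names), values, bounds)
    surface = MorseTorsionSurface(pv, f, alpha)
    meta = {**meta, "zeta_star": pv.as_dict(), "alpha": float(alpha),
            "d_scale": float(d_scale), "wells": "morse"}
    return surface, meta


def perturb_params(pv: ParamVector, relative_scale: float, seed: int
                   ) -> tuple[ParamVector, dict]:
    """Multiplicative perturbation of a parameter vector within its bounds.

    Emulates a degraded starting parametrization.  Returns the perturbed
    vector and a report with the percent deviation per parameter; values
    escaping the bounds are clipped and flagged.
    """
    if relative_scale < 0:
        raise ValueError("relative_scale must be >= 0")
    rng = np.random.default_rng(seed)
    factors = 1.0 + rng.uniform(-relative_scale, relative_scale, pv.dim)
    raw = pv.values * factors
    clipped = np.clip(raw, pv.bounds[:, 0], pv.bounds[:, 1])
    flagged = [n for n, r, c in zip(pv.names, raw, clipped) if r != c]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(pv.values != 0.0, 100.0 * (clipped - pv.values) / pv.values, 0.0)
    report = {"percent_deviation": dict(zip(pv.names, map(float, pct))),
              "clipped": flagged, "seed": int(seed), "scale": float(relative_scale)}
    return pv.with_values(clipped), report


# ---------------------------------------------------------------------------
# XYZ plumbing (Angstrom Cartesians exchanged with external programs)


def write_xyz(path, symbols, coords, comment: str = "", append: bool = False) -> None:
    coords = np.asarray(coords, float).reshape(-1, 3)
    with open(path, "a" if append else "w") as fh:
        fh.write(f"{len(symbols)}\n{comment}\n")
        for s, (x, y, z) in zip(symbols, coords):
            fh.write(f"{s} {x:.10f} {y:.10f} {z:.10f}\n")


def read_xyz(path) -> list[tuple[list[str], np.ndarray, str]]:
    """Read a (possibly multi-frame) XYZ file into (symbols, coords, comment) frames."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        block = lines[i + 2:i + 2 + n]
        symbols = [ln.split()[0] for ln in block]
        coords = np.array([[float(x) for x in ln.split()[1:4]] for ln in block])
        frames.append((symbols, coords, comment))
        i += 2 + n
    return frames


class ExternalBackendError(RuntimeError):
    """External program failed or produced unparseable output for a geometry."""

    def __init__(self, message, geometry=None):
        super().__init__(message)
        self.geometry = geometry


class ExternalBackend(SurfaceBackend):
    """Backend that dispatches each energy call to an external program.

    ``program_spec`` is a mapping with keys:

    - ``command``: argv list; ``{input}`` is replaced by the input path
    - ``template``: input-file template with ``{geometry}`` and ``{params}``
    - ``energy_regex``: regex whose group 1 is the energy
    - ``dof_count``, optional ``coord_names``, ``periodic``, ``energy_scale``
    - optional ``param_format``: one-per-line ``"{name} {value}"`` by default
    - optional ``failure_regex``: SCF-failure sentinel in the output
    """

    def __init__(self, program_spec: dict, workdir):
        self.spec = dict(program_spec)
        self.workdir = Path(workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        self.dof_count = int(self.spec["dof_count"])
        self.coord_names = list(self.spec.get(
            "coord_names", [f"q{i}" for i in range(self.dof_count)]))
        self.periodic = np.asarray(self.spec.get("periodic", [False] * self.dof_count), bool)
        self.params: ParamVector | None = self.spec.get("params")
        self._cache: dict = {}
        self.n_process_launches = 0

    def _key(self, geometry, zeta):
        h = hashlib.sha256()
        h.update(np.asarray(geometry, float).tobytes())
        if zeta is not None:
            h.update(np.asarray(zeta, float).tobytes())
        return h.hexdigest()

    def _format_params(self, zeta) -> str:
        if zeta is None:
            return ""
        names = (self.params.names if self.params is not None
                 else [f"p{i}" for i in range(len(zeta))])
        fmt = self.spec.get("param_format", "{name} {value:.12g}")
        return "\n".join(fmt.format(name=n, value=v) for n, v in zip(names, zeta))

    def energy(self, geometry, zeta=None) -> float:
        key = self._key(geometry, zeta)
        if key in self._cache:
            return self._cache[key]
        geom_str = "\n".join(f"{x:.12f}" for x in np.asarray(geometry, float).ravel())
        text = self.spec["template"].format(geometry=geom_str,
                                            params=self._format_params(zeta))
        inp = self.workdir / f"job_{key[:16]}.inp"
        inp.write_text(text)
        cmd = [c.replace("{input}", str(inp)) for c in self.spec["command"]]
        self.n_process_launches += 1
        proc = subprocess.run(cmd, capture_output=True, text=True, cwd=self.workdir)
        if proc.returncode != 0:
            raise ExternalBackendError(
                f"external program exited with {proc.returncode}: {proc.stderr[:500]}",
                geometry=np.asarray(geometry, float))
        out = proc.stdout
        fail = self.spec.get("failure_regex")
        if fail and re.search(fail, out):
            raise ExternalBackendError("external program reported a failed calculation",
                                       geometry=np.asarray(geometry, float))
        m = re.search(self.spec["energy_regex"], out)
        if not m:
            raise ExternalBackendError(
                f"could not parse energy from output: {out[:500]!r}",
                geometry=np.asarray(geometry, float))
        e = float(m.group(1)) * float(self.spec.get("energy_scale", 1.0))
        self._cache[key] = e
        return e


def external_adapter(program_spec: dict, workdir) -> ExternalBackend:
    """Wrap an external electronic-structure program as a SurfaceBackend."""
    return ExternalBackend(program_spec, workdir)
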