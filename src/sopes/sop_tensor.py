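"""Tucker-format potential container, evaluation, mode products and file I/O.

A potential on a direct-product grid is stored as a core tensor C of shape
(m_1, ..., m_f) together with per-DOF factor matrices v^(kappa) of shape
(N_kappa, m_kappa) whose columns are single-particle potentials.  The value
at a grid point (i_1, ..., i_f) is the contraction

    V[i] = sum_{j1..jf} C[j1..jf] * prod_kappa v^(kappa)[i_kappa, j_kappa]

The storage cost, |C| + sum N_kappa m_kappa, is orders of magnitude below
the prod N_kappa cost of the raw tensor for realistic grids.

The SOP file format (see ``write_sop``) is a small self-describing container
with a JSON header (grid definitions, shapes, units, provenance, payload
checksum) and either a text payload (hexadecimal floats; round-trips
bit-exactly) or a little-endian float64 binary payload.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from sopes.grids import DVRGrid, build_dvr

__all__ = ["TuckerPotential", "mode_product", "write_sop", "read_sop", "SOPFormatError"]

_MAGIC = "SOPES-SOP"
_VERSION = 1


class SOPFormatError(ValueError):
    """Raised on malformed, truncated or checksum-failing SOP files."""


def mode_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` product of a tensor with a matrix.

    ``matrix`` has shape (J, I_mode); the result replaces extent I_mode of
    ``tensor`` by J.  Applying an identity matrix is a no-op.
    """
    tensor = np.asarray(tensor)
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != tensor.shape[mode]:
        raise ValueError(
            f"matrix shape {matrix.shape} not conformable with tensor extent "
            f"{tensor.shape[mode]} along mode {mode}")
    out = np.tensordot(matrix, tensor, axes=(1, mode))
    return np.moveaxis(out, 0, mode)


@dataclass
class TuckerPotential:
    """A potential in Tucker (sum-of-products) form on declared grids."""

    core: np.ndarray
    factors: list[np.ndarray]
    grids: list[DVRGrid] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.core = np.asarray(self.core, dtype=float)
        self.factors = [np.asarray(v, dtype=float) for v in self.factors]
        if self.core.ndim != len(self.factors):
            raise ValueError("core order and number of factor matrices disagree")
        for k, v in enumerate(self.factors):
            if v.ndim != 2 or v.shape[1] != self.core.shape[k]:
                raise ValueError(
                    f"factor {k} shape {v.shape} incompatible with core shape "
                    f"{self.core.shape}")
            if self.grids is not None and v.shape[0] != self.grids[k].n_points:
                raise ValueError(f"factor {k} rows do not match grid size")

    @property
    def f(self) -> int:
        return self.core.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        """Primitive-grid shape (N_1, ..., N_f)."""
        return tuple(v.shape[0] for v in self.factors)

    @property
    def ranks(self) -> tuple[int, ...]:
        return self.core.shape

    def evaluate(self, index: tuple[int, ...]) -> float:
        """Tucker contraction at one primitive-grid index."""
        if len(index) != self.f:
            raise IndexError(f"index length {len(index)} != order {self.f}")
        out = self.core
        for k in range(self.f - 1, -1, -1):
            i = int(index[k])
            if not 0 <= i < self.factors[k].shape[0]:
                raise IndexError(f"index {i} out of bounds for mode {k}")
            out = out @ self.factors[k][i, :]
        return float(out)

    def evaluate_many(self, indices: np.ndarray) -> np.ndarray:
        """Vectorized evaluation at an (n, f) array of grid indices."""
        indices = np.asarray(indices, dtype=int)
        rows = self.factors[0][indices[:, 0], :]  # (n, m_0)
        out = np.tensordot(rows, self.core, axes=(1, 0))  # (n, m_1, ..., m_{f-1})
        for k in range(1, self.f):
            rows = self.factors[k][indices[:, k], :]
            out = np.einsum("nj,nj...->n...", rows, out)
        return out

    def full_tensor(self) -> np.ndarray:
        """Dense reconstruction on the whole primitive grid (small grids only)."""
        out = self.core
        for k, v in enumerate(self.factors):
            out = mode_product(out, v, k)
        return out

    def storage_size(self) -> int:
        """Number of stored reals: |core| + sum of factor entries."""
        return int(self.core.size + sum(v.size for v in self.factors))

    def summary(self) -> str:
        """Human-readable expansion summary (ranks and natural-potential weights)."""
        lines = [
            f"Tucker potential: f={self.f}, grid shape {self.shape}, ranks {self.ranks}",
            f"storage {self.storage_size()} reals vs {int(np.prod(self.shape))} on the full grid",
        ]
        for k, v in enumerate(self.factors):
            w = np.linalg.norm(v, axis=0)
            top = ", ".join(f"{x:.3g}" for x in sorted(w, reverse=True)[:5])
            lines.append(f"  mode {k}: {v.shape[1]} single-particle potentials, "
                         f"largest column norms [{top}]")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# file format


def _payload_arrays(pot: TuckerPotential) -> list[np.ndarray]:
    return [pot.core] + list(pot.factors)


def _text_payload(arrays: list[np.ndarray]) -> str:
    lines = []
    for a in arrays:
        lines.extend(float(x).hex() for x in a.ravel())
    return "\n".join(lines) + "\n"


def _binary_payload(arrays: list[np.ndarray]) -> bytes:
    return b"".join(np.ascontiguousarray(a, dtype="<f8").tobytes() for a in arrays)


def write_sop(pot: TuckerPotential, path, dialect: str = "text") -> None:
    """Write a Tucker potential to an SOP file (``text`` or ``binary`` dialect)."""
    if dialect not in ("text", "binary"):
        raise ValueError(f"unknown dialect {dialect!r}")
    arrays = _payload_arrays(pot)
    if dialect == "text":
        payload = _text_payload(arrays).encode()
    else:
        payload = _binary_payload(arrays)
    header = {
        "core_shape": list(pot.core.shape),
        "factor_shapes": [list(v.shape) for v in pot.factors],
        "grids": [g.to_config() for g in pot.grids] if pot.grids is not None else None,
        "meta": pot.meta,
        "checksum": hashlib.sha256(payload).hexdigest(),
    }
    with open(path, "wb") as fh:
        fh.write(f"{_MAGIC} {_VERSION} {dialect}\n".encode())
        fh.write(json.dumps(header, sort_keys=True).encode() + b"\n")
        fh.write(payload)


def read_sop(path) -> TuckerPotential:
    """Read an SOP file, verifying the payload checksum and declared shapes."""
    with open(path, "rb") as fh:
        magic_line = fh.readline().decode(errors="replace").split()
        if len(magic_line) != 3 or magic_line[0] != _MAGIC:
            raise SOPFormatError(f"not an SOP file: {path}")
        dialect = magic_line[2]
        try:
            header = json.loads(fh.readline().decode())
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise SOPFormatError(f"unreadable SOP header in {path}: {exc}") from exc
        payload = fh.read()
    if hashlib.sha256(payload).hexdigest() != header["checksum"]:
        raise SOPFormatError(f"checksum mismatch in {path} (truncated or corrupted)")
    shapes = [tuple(header["core_shape"])] + [tuple(s) for s in header["factor_shapes"]]
    n_expected = sum(int(np.prod(s)) for s in shapes)
    if dialect == "text":
        values = np.array([float.fromhex(tok) for tok in payload.decode().split()])
    elif dialect == "binary":
        values = np.frombuffer(payload, dtype="<f8").astype(float)
    else:
        raise SOPFormatError(f"unknown SOP dialect {dialect!r}")
    if values.size != n_expected:
        raise SOPFormatError(
            f"payload holds {values.size} values, header declares {n_expected}")
    arrays, ofs = [], 0
    for s in shapes:
        n = int(np.prod(s))
        arrays.append(values[ofs:ofs + n].reshape(s))
        ofs += n
    grids = None
    if header.get("grids") is not None:
        grids = [build_dvr(g["kind"], g["n_points"], (g["first"], g["last"]), name=g.get("name", ""))
                 for g in header["grids"]]
    return TuckerPotential(arrays[0], arrays[1:], grids=grids, meta=header.get("meta", {}))
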