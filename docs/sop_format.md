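# SOP file format

`sopes` stores Tucker-form potentials in a small self-describing container
written by `sopes.sop_tensor.write_sop` and read by `read_sop`.

## Layout

```
SOPES-SOP 1 <dialect>\n          magic, format version, dialect (text|binary)
<header JSON>\n                  one line, UTF-8
<payload>                        core tensor then factor matrices, in order
```

The header object holds:

| key             | meaning                                              |
|-----------------|------------------------------------------------------|
| `core_shape`    | core tensor shape `[m_1, ..., m_f]`                  |
| `factor_shapes` | per-DOF factor shapes `[[N_k, m_k], ...]`            |
| `grids`         | per-DOF grid configs (name, kind, n_points, first, last) or null |
| `meta`          | provenance: builder, stride, ranks, energy units, …  |
| `checksum`      | SHA-256 hex digest of the raw payload bytes          |

Arrays are serialized row-major (C order), core first, then the factor
matrix of each DOF in order.

## Dialects

- **text** — one value per line as a hexadecimal float (`float.hex()`),
  e.g. `0x1.5bf0a8b145769p+1`. Round-trips bit-exactly and diffs cleanly;
  used for fixtures.
- **binary** — little-endian IEEE-754 8-byte reals, no separators.

## Integrity

`read_sop` verifies the checksum (truncation or corruption raises
`SOPFormatError`) and that the payload length matches the declared shapes.
Energies are in the units declared in `meta` (cm⁻¹ by convention, relative
to the reference geometry recorded by the builder).
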