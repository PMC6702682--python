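"""Published HONO cis-trans benchmark inputs used for metric checks.

The HONO cis-trans isomerization is the standard 6D benchmark for
sum-of-products PES construction.  This module collects the published
benchmark inputs the toolkit's bookkeeping and metrics are exercised
against: the 6D DVR primitive-grid definition (internal coordinates:
three distances, two cosines of bending angles, one torsion), and the 20
lowest vibrational eigenvalues (plus the ground-state zero row) obtained on
surfaces of increasing reparametrization quality -- the unparametrized
semiempirical start (zeta_PM7), two refit stages (zeta_53, zeta_1084, the
subscript counting fitting points), and the analytical reference surface.
"""

from __future__ import annotations

from sopes.grids import DVRGrid, build_dvr

__all__ = [
    "HONO_GRID_SPEC",
    "hono_grids",
    "HONO_EIGENVALUES_CM1",
    "HONO_EIGEN_RMSE_CM1",
    "TRAJECTORY_PROTOCOL",
]

#: 6D DVR primitive grid of the benchmark (name, DVR family, N, first, last);
#: the torsion range [0, pi] exploits the cis-trans symmetry plane.
HONO_GRID_SPEC = [
    ("d_OH", "harmonic", 18, 1.30, 2.45),
    ("d_NO", "harmonic", 13, 1.90, 2.60),
    ("u2", "harmonic", 13, -0.65, -0.10),
    ("d_ON", "harmonic", 16, 2.10, 3.25),
    ("u1", "harmonic", 18, -0.65, 0.25),
    ("phi", "cosine", 32, 0.0, 3.141592653589793),
]


def hono_grids() -> list[DVRGrid]:
    """Build the benchmark 6D primitive grid."""
    return [build_dvr(kind, n, (first, last), name=name)
            for name, kind, n, first, last in HONO_GRID_SPEC]


#: 21 lowest vibrational eigenvalues (cm^-1, relative to each ground state)
#: per surface; keys: semiempirical start, two refit stages, reference.
HONO_EIGENVALUES_CM1 = {
    "zeta_pm7": [
        0.0, 593.6, 794.3, 1070.6, 1151.5, 1186.3, 1365.9, 1403.1, 1641.3,
        1659.6, 1751.1, 1773.1, 1811.5, 1869.9, 1968.7, 2011.4, 2060.3,
        2118.1, 2136.5, 2226.5, 2253.3,
    ],
    "zeta_53": [
        0.0, 163.0, 604.7, 693.2, 706.9, 888.9, 1134.3, 1204.8, 1221.6,
        1263.0, 1308.9, 1361.6, 1395.7, 1424.9, 1426.3, 1612.4, 1656.9,
        1698.3, 1748.6, 1842.0, 1853.0,
    ],
    "zeta_1084": [
        0.0, 88.5, 597.1, 703.9, 822.3, 917.9, 1012.5, 1189.7, 1234.7,
        1317.9, 1363.5, 1417.2, 1451.1, 1530.5, 1607.7, 1633.9, 1690.9,
        1743.0, 1778.7, 1785.8, 1807.3,
    ],
    "analytical": [
        0.0, 94.1, 600.8, 710.7, 795.9, 944.1, 1055.4, 1188.1, 1264.9,
        1306.6, 1312.8, 1385.3, 1404.8, 1547.9, 1574.9, 1640.9, 1689.9,
        1726.0, 1762.4, 1779.7, 1829.0,
    ],
}

#: published eigenvalue RMSEs (cm^-1) of each column against the reference,
#: over all 21 rows including the zero row
HONO_EIGEN_RMSE_CM1 = {"zeta_pm7": 360.2, "zeta_53": 58.4, "zeta_1084": 24.5}

#: classical validation protocol: per isomer, per vibrational energy
#: (kcal/mol), number of trajectories; 1 ps at a 5 fs step, initial frame
#: stored, giving 80 trajectories and 16,080 geometries in total
TRAJECTORY_PROTOCOL = {
    "isomers": 2,
    "energies_kcalmol": (5.0, 10.0, 15.0, 20.0),
    "trajectories_per_condition": 10,
    "t_total_fs": 1000.0,
    "dt_fs": 5.0,
}
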