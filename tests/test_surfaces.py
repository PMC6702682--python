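"""Toy surface family, parameter vectors and the external-program adapter."""

import os
import stat

import numpy as np
import pytest

from sopes.stationary_vib import numerical_hessian
from sopes.surfaces import (
    ExternalBackendError,
    ParamVector,
    ToyTorsionSurface,
    external_adapter,
    perturb_params,
    read_xyz,
    toy_reference,
    toy_reference_morse,
    write_xyz,
)


def make_surface(f=3, c1=0.0, c2=1000.0, couplings=True, d=0.1):
    nc = f - 1
    names = ToyTorsionSurface.param_names(f)
    a = np.full(nc, 4.0e5)
    dvec = np.full(nc, d)
    b = (np.full(nc * (nc - 1) // 2, 2.0e4) if couplings
         else np.zeros(nc * (nc - 1) // 2))
    q0 = np.linspace(1.5, 2.5, nc)
    vals = np.concatenate([a, dvec, b, [c1, c2], q0])
    lo = np.where(vals >= 0, vals * 0.5 - 1.0, vals * 1.5 - 1.0)
    hi = np.where(vals >= 0, vals * 1.5 + 1.0, vals * 0.5 + 1.0)
    return ToyTorsionSurface(ParamVector(names, vals, np.column_stack([lo, hi])), f)


class TestToyFamily:
    def test_barrier_height_two_c2_when_symmetric(self):
        surf = make_surface(c1=0.0, c2=1234.5)
        top = surf.energy(surf.relaxed_chain(np.pi / 2))
        bottom = surf.energy(surf.relaxed_chain(0.0))
        assert top - bottom == pytest.approx(2 * 1234.5, rel=1e-12)

    def test_separability_without_couplings(self):
        surf = make_surface(couplings=False, d=0.0)
        g = np.array([1.7, 2.6, 1.1])
        parts = (surf.energy(np.array([1.7, 2.5, 0.0]))  # q1 displaced only
                 + surf.energy(np.array([1.5, 2.6, 0.0]))
                 + surf.energy(np.array([1.5, 2.5, 1.1])))
        assert surf.energy(g) == pytest.approx(parts, rel=1e-12)

    def test_gradient_zero_at_minimum(self):
        surf = make_surface()
        assert np.abs(surf.gradient(surf.relaxed_chain(0.0))).max() < 1e-10

    def test_analytic_hessian_matches_numerical(self, toy3):
        surf, _ = toy3
        g = surf.relaxed_chain(0.7) + 0.05
        num = numerical_hessian(surf, g, step=1e-4, richardson=True)
        assert np.allclose(surf.hessian(g), num, atol=1e-4 * np.abs(num).max())

    def test_coupling_appears_in_hessian(self):
        surf = make_surface()
        h = surf.hessian(surf.relaxed_chain(0.0))
        assert h[0, 1] == pytest.approx(2.0e4, rel=1e-10)

    def test_periodicity_of_torsion(self, toy3):
        surf, _ = toy3
        g = np.array([1.8, 2.2, 0.9])
        g2 = g.copy()
        g2[-1] += 2 * np.pi
        assert surf.energy(g) == pytest.approx(surf.energy(g2), rel=1e-12)

    def test_energy_many_matches_scalar(self, toy3):
        surf, _ = toy3
        rng = np.random.default_rng(0)
        geoms = rng.uniform(1.0, 3.0, size=(20, 3))
        assert np.allclose(surf.energy_many(geoms),
                           [surf.energy(g) for g in geoms], rtol=1e-12)

    def test_reference_deterministic_per_seed(self):
        s1, m1 = toy_reference(3)
        s2, m2 = toy_reference(3)
        s3, _ = toy_reference(4)
        assert np.array_equal(s1.params.values, s2.params.values)
        assert not np.array_equal(s1.params.values, s3.params.values)

    def test_zeta_override_equivalent_to_instance_params(self, toy3):
        surf, _ = toy3
        g = np.array([1.6, 2.1, 2.0])
        assert surf.energy(g, surf.params.values) == surf.energy(g)


class TestMorseVariant:
    def test_reduces_to_harmonic_at_small_displacement(self, toy3, morse3):
        harm, _ = toy3
        mors, _ = morse3
        g0 = mors.relaxed_chain(0.0)
        assert mors.energy(g0) == pytest.approx(0.0, abs=1e-9)
        assert np.abs(mors.gradient(g0)).max() < 1e-9

    def test_asymmetric_wells(self, morse3):
        surf, _ = morse3
        g0 = surf.relaxed_chain(0.0)
        e_plus = surf.energy(g0 + np.array([0.2, 0.0, 0.0]))
        e_minus = surf.energy(g0 - np.array([0.2, 0.0, 0.0]))
        assert e_plus != pytest.approx(e_minus, rel=1e-3)

    def test_gradient_matches_finite_difference(self, morse3):
        surf, _ = morse3
        g = surf.relaxed_chain(1.0) + 0.07
        num = np.zeros(3)
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1e-6
            num[i] = (surf.energy(g + e) - surf.energy(g - e)) / 2e-6
        assert np.allclose(surf.gradient(g), num, rtol=1e-5, atol=1e-3)

    def test_energy_many_matches_scalar(self, morse3):
        surf, _ = morse3
        rng = np.random.default_rng(1)
        geoms = rng.uniform(1.2, 2.8, size=(15, 3))
        assert np.allclose(surf.energy_many(geoms),
                           [surf.energy(g) for g in geoms], rtol=1e-12)

    def test_morse_reference_deterministic(self):
        a, _ = toy_reference_morse(2)
        b, _ = toy_reference_morse(2)
        assert np.array_equal(a.params.values, b.params.values)
        assert np.array_equal(a.alphas, b.alphas)


class TestPerturbParams:
    def test_zero_scale_unchanged(self, toy3):
        surf, _ = toy3
        pv, report = perturb_params(surf.params, 0.0, seed=1)
        assert np.array_equal(pv.values, surf.params.values)
        assert all(v == 0.0 for v in report["percent_deviation"].values())

    def test_bounded_deviation(self, toy3):
        surf, _ = toy3
        pv, report = perturb_params(surf.params, 0.2, seed=7)
        pct = np.array(list(report["percent_deviation"].values()))
        assert np.all(np.abs(pct) <= 20.0 + 1e-9)
        assert np.all(pv.values >= pv.bounds[:, 0])
        assert np.all(pv.values <= pv.bounds[:, 1])

    def test_two_seeds_differ(self, toy3):
        surf, _ = toy3
        a, _ = perturb_params(surf.params, 0.2, seed=1)
        b, _ = perturb_params(surf.params, 0.2, seed=2)
        assert not np.array_equal(a.values, b.values)


class TestParamVector:
    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParamVector(["x"], [2.0], [[0.0, 1.0]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ParamVector(["x", "y"], [0.5], [[0.0, 1.0]])


def _mock_program(tmp_path, body):
    exe = tmp_path / "mock_qc.sh"
    exe.write_text("#!/bin/sh\n" + body)
    exe.chmod(exe.stat().st_mode | stat.S_IEXEC)
    return str(exe)


@pytest.fixture
def adapter_spec(tmp_path):
    exe = _mock_program(tmp_path, 'echo "FINAL ENERGY = -42.125"\n')
    return {
        "command": [exe, "{input}"],
        "template": "geom\n{geometry}\nparams\n{params}\n",
        "energy_regex": r"FINAL ENERGY =\s*(-?\d+\.?\d*)",
        "dof_count": 3,
    }


class TestExternalAdapter:
    def test_mock_energy_parsed(self, adapter_spec, tmp_path):
        backend = external_adapter(adapter_spec, tmp_path / "wd")
        assert backend.energy(np.array([1.0, 2.0, 3.0])) == pytest.approx(-42.125)

    def test_cache_hit_launches_no_process(self, adapter_spec, tmp_path):
        backend = external_adapter(adapter_spec, tmp_path / "wd")
        g = np.array([1.0, 2.0, 3.0])
        backend.energy(g)
        n = backend.n_process_launches
        backend.energy(g)
        assert backend.n_process_launches == n

    def test_distinct_params_are_distinct_cache_keys(self, adapter_spec, tmp_path):
        backend = external_adapter(adapter_spec, tmp_path / "wd")
        g = np.array([1.0, 2.0, 3.0])
        backend.energy(g, np.array([0.5]))
        n = backend.n_process_launches
        backend.energy(g, np.array([0.6]))
        assert backend.n_process_launches == n + 1

    def test_malformed_output_raises_with_geometry(self, tmp_path):
        exe = _mock_program(tmp_path, 'echo "no energy here"\n')
        spec = {"command": [exe, "{input}"], "template": "{geometry}\n{params}",
                "energy_regex": r"FINAL ENERGY =\s*(-?\d+\.?\d*)", "dof_count": 2}
        backend = external_adapter(spec, tmp_path / "wd")
        with pytest.raises(ExternalBackendError) as err:
            backend.energy(np.array([1.0, 2.0]))
        assert np.array_equal(err.value.geometry, [1.0, 2.0])

    def test_nonzero_exit_raises(self, tmp_path):
        exe = _mock_program(tmp_path, "exit 3\n")
        spec = {"command": [exe, "{input}"], "template": "{geometry}\n{params}",
                "energy_regex": r"(\d+)", "dof_count": 1}
        backend = external_adapter(spec, tmp_path / "wd")
        with pytest.raises(ExternalBackendError):
            backend.energy(np.array([1.0]))

    def test_failure_sentinel_detected(self, tmp_path):
        exe = _mock_program(tmp_path, 'echo "SCF FAILED"; echo "ENERGY = 1.0"\n')
        spec = {"command": [exe, "{input}"], "template": "{geometry}\n{params}",
                "energy_regex": r"ENERGY =\s*(-?\d+\.?\d*)", "dof_count": 1,
                "failure_regex": "SCF FAILED"}
        backend = external_adapter(spec, tmp_path / "wd")
        with pytest.raises(ExternalBackendError):
            backend.energy(np.array([1.0]))


class TestXyzIO:
    def test_roundtrip_multiframe(self, tmp_path):
        path = tmp_path / "frames.xyz"
        rng = np.random.default_rng(0)
        c1, c2 = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        write_xyz(path, ["H", "O", "N", "O"], c1, comment="frame 0")
        write_xyz(path, ["H", "O", "N", "O"], c2, comment="frame 1", append=True)
        frames = read_xyz(path)
        assert len(frames) == 2
        assert frames[0][0] == ["H", "O", "N", "O"]
        assert np.allclose(frames[1][1], c2, atol=1e-9)
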