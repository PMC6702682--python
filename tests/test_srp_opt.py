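"""Objective functions, weights, and the global/local refitting protocol."""

import numpy as np
import pytest

from sopes import srp_opt
from sopes.refset import RefEntry, ReferenceDataset
from sopes.srp_opt import (
    ObjectiveSpec,
    chi0,
    chi1,
    cumulative_rmse,
    energy_rmse,
    global_optimize,
    local_optimize,
    staged_fit,
    step_weight,
)
from sopes.stationary_vib import PointKind, refine_stationary
from sopes.surfaces import SurfaceBackend, perturb_params, toy_reference


class OffsetBackend(SurfaceBackend):
    """Returns a fixed offset everywhere: residuals equal the references."""

    dof_count = 1
    coord_names = ["q"]
    periodic = np.array([False])

    def __init__(self, offset=0.0):
        self.offset = offset

    def energy(self, geometry, zeta=None):
        return self.offset


def spec_with_refs(energies, backend=None, **kwargs):
    ds = ReferenceDataset([RefEntry(np.array([float(i)]), energy=e, tag="core")
                           for i, e in enumerate(energies)])
    return ObjectiveSpec(ds, backend or OffsetBackend(), np.zeros(1),
                         alpha_E=np.inf, **kwargs)


class TestStepWeight:
    def test_continuity_at_alpha(self):
        assert step_weight(3.0, 3.0, -2.0) == pytest.approx(1.0)
        assert step_weight(3.0 + 1e-12, 3.0, -2.0) == pytest.approx(1.0, abs=1e-9)

    def test_beta_zero_flat(self):
        assert np.all(step_weight(np.array([-5.0, 0.0, 100.0]), 0.0, 0.0) == 1.0)

    def test_closed_form_value(self):
        assert step_weight(2.0, 0.0, -1.0) == pytest.approx(np.exp(-2.0))

    def test_below_threshold_unity(self):
        assert np.all(step_weight(np.array([-1.0, 0.5]), 1.0, -3.0) == 1.0)


class TestChi:
    def test_chi0_unit_weight_arithmetic(self):
        spec = spec_with_refs([3.0, 4.0])
        assert chi0(np.zeros(1), spec) == pytest.approx((9 + 16) / 2)

    def test_chi1_same_on_energy_only(self):
        spec = spec_with_refs([3.0, 4.0])
        assert chi1(np.zeros(1), spec) == pytest.approx(12.5)

    def test_perfect_fit_zero(self, toy3):
        surf, _ = toy3
        g0 = surf.relaxed_chain(0.0)
        rng = np.random.default_rng(0)
        geoms = g0 + rng.uniform(-0.05, 0.05, size=(10, 3))
        e0 = surf.energy(g0)
        ds = ReferenceDataset([RefEntry(g, energy=surf.energy(g) - e0, tag="core")
                               for g in geoms])
        spec = ObjectiveSpec(ds, surf, g0)
        assert chi1(surf.params.values, spec) == pytest.approx(0.0, abs=1e-12)
        assert chi0(surf.params.values, spec) == pytest.approx(0.0, abs=1e-12)

    def test_chi0_chi1_differ_with_frequency_terms(self, toy3):
        """Distinct normalizations: the two forms disagree on asymmetric data."""
        surf, _ = toy3
        g0 = surf.relaxed_chain(0.0)
        sp = refine_stationary(surf, None, g0, PointKind.MINIMUM)
        ds = ReferenceDataset([RefEntry(g0 + 0.02, energy=10.0, tag="core")])
        term = srp_opt.FreqTerm(g0, PointKind.MINIMUM,
                                sp.frequencies + np.array([5.0, 5.0, 5.0]))
        spec0 = ObjectiveSpec(ds, surf, g0, freq_terms=[term], alpha_F=np.inf)
        a = chi0(surf.params.values, spec0)
        b = chi1(surf.params.values, spec0)
        assert a != pytest.approx(b, rel=1e-6)

    def test_penalty_on_refinement_failure(self, toy3):
        surf, _ = toy3
        ds = ReferenceDataset([RefEntry(surf.relaxed_chain(0.0), energy=0.0,
                                        tag="core")])
        # a guess far from any stationary point with Newton disabled by the
        # bound geometry: TS guess labelled minimum fails index validation
        term = srp_opt.FreqTerm(surf.ts_guess(), PointKind.MINIMUM,
                                np.ones(3) * 100.0)
        spec = ObjectiveSpec(ds, surf, surf.relaxed_chain(0.0), freq_terms=[term])
        assert chi0(surf.params.values, spec) == srp_opt.CHI_PENALTY
        assert spec.flags

    def test_nonnegative_and_permutation_invariant(self):
        spec_a = spec_with_refs([1.0, -2.0, 3.0])
        spec_b = spec_with_refs([3.0, 1.0, -2.0])
        va, vb = chi1(np.zeros(1), spec_a), chi1(np.zeros(1), spec_b)
        assert va >= 0.0
        assert va == pytest.approx(vb)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            ObjectiveSpec(ReferenceDataset(), OffsetBackend(), np.zeros(1))


class TestLocalOptimize:
    def test_quadratic_minimizer_found(self):
        bounds = np.array([[-5.0, 5.0]])
        x, f = local_optimize(lambda z: float((z[0] - 1.3) ** 2), bounds,
                              np.array([4.0]), max_evals=2000)
        assert x[0] == pytest.approx(1.3, abs=1e-8)

    def test_never_worse_than_start(self):
        bounds = np.array([[-1.0, 1.0]] * 2)
        rng = np.random.default_rng(0)

        def rugged(z):
            return float(np.sum(z**2) + 0.5 * np.sin(40 * z[0]))

        x0 = rng.uniform(-1, 1, 2)
        x, f = local_optimize(rugged, bounds, x0, max_evals=50)
        assert f <= rugged(x0) + 1e-12

    def test_start_at_optimum_stays(self):
        bounds = np.array([[-2.0, 2.0]])
        x, f = local_optimize(lambda z: float(z[0] ** 2), bounds,
                              np.array([0.0]), max_evals=200)
        assert f <= 1e-16


def modified_ackley(z):
    """2D multiwell test function (many local minima, global at the center)."""
    z = np.asarray(z, float)
    return float(-20 * np.exp(-0.2 * np.sqrt(np.mean(z**2)))
                 - np.exp(np.mean(np.cos(2 * np.pi * z))) + 20 + np.e)


class TestGlobalOptimize:
    def test_convex_bowl_recovered_any_seed(self):
        bounds = np.array([[-3.0, 3.0], [-3.0, 3.0]])
        target = np.array([0.7, -1.1])

        def bowl(z):
            return float(np.sum((z - target) ** 2))

        for seed in (0, 1, 2):
            x, f, _ = global_optimize(bowl, bounds, n_starts=8, max_evals=4000,
                                      seed=seed)
            assert np.allclose(x, target, atol=1e-6)

    def test_beats_pure_random_search(self):
        bounds = np.array([[-4.0, 4.0], [-4.0, 4.0]])
        rng = np.random.default_rng(42)
        random_best = min(modified_ackley(rng.uniform(-4, 4, 2))
                          for _ in range(100))
        x, f, report = global_optimize(modified_ackley, bounds, n_starts=20,
                                       max_evals=6000, seed=0)
        assert f <= random_best
        assert report["descents"] >= 1

    def test_single_start_is_local_descent(self):
        bounds = np.array([[-2.0, 2.0]])
        x, f, report = global_optimize(lambda z: float((z[0] - 0.5) ** 2),
                                       bounds, n_starts=1, max_evals=2000, seed=3)
        assert report["descents"] == 1
        assert x[0] == pytest.approx(0.5, abs=1e-6)

    def test_budget_validated(self):
        with pytest.raises(ValueError):
            global_optimize(lambda z: 0.0, np.array([[0.0, 1.0]]), n_starts=10,
                            max_evals=5)


def recovery_experiment(surf_seed, pert_seed, opt_seed, stages=3):
    surf, _ = toy_reference(surf_seed, f=3)
    from sopes import refset
    min1 = refine_stationary(surf, None, surf.relaxed_chain(0.0), PointKind.MINIMUM)
    min2 = refine_stationary(surf, None, surf.relaxed_chain(np.pi), PointKind.MINIMUM)
    ts = refine_stationary(surf, None, surf.ts_guess(), PointKind.TS)
    sps = [min1, min2, ts]
    e0 = min(min1.energy, min2.energy)
    ref_geom = min1.geometry if min1.energy <= min2.energy else min2.geometry
    diag = np.diag(min1.hessian)
    deltas = np.append(np.sqrt(2 * 3000.0 / diag[:-1]), 0.8)
    core = refset.ReferenceDataset([refset.RefEntry(sp.geometry, tag="core")
                                    for sp in sps])
    clouds = [refset.random_fD(np.column_stack([sp.geometry - deltas,
                                                sp.geometry + deltas]),
                               15, opt_seed + 10 + i, tag="core")
              for i, sp in enumerate(sps)]
    d1 = [refset.grid_displacements(sp, 1, [0, 1, 2], deltas, 4) for sp in sps]
    d2 = [refset.grid_displacements(sp, 2, [0, 1, 2], deltas, 3) for sp in sps]
    parts = [[core] + clouds, [core] + clouds + d1, [core] + clouds + d1 + d2]
    specs = []
    for i, comp in enumerate(parts[:stages]):
        ds, _ = refset.assemble_stage(f"s{i}", comp)
        specs.append(ObjectiveSpec(ds.with_energies(surf, reference_energy=e0),
                                   surf, ref_geom))
    z0, _ = perturb_params(surf.params, 0.2, seed=pert_seed)
    ledger = staged_fit(specs, surf.params.bounds, z0.values, n_starts=12,
                        global_evals=3000, local_evals=2000, seed=opt_seed)
    zstar = surf.params.values
    return (ledger, z0,
            np.linalg.norm(ledger.best_zeta - zstar) / np.linalg.norm(zstar),
            specs)


class TestStagedFit:
    def test_warm_restart_never_worse_on_same_data(self, toy3):
        surf, _ = toy3
        g0 = surf.relaxed_chain(0.0)
        rng = np.random.default_rng(1)
        geoms = g0 + rng.uniform(-0.05, 0.05, size=(20, 3))
        e0 = surf.energy(g0)
        ds = ReferenceDataset([RefEntry(g, energy=surf.energy(g) - e0, tag="core")
                               for g in geoms])
        specs = [ObjectiveSpec(ds, surf, g0), ObjectiveSpec(ds, surf, g0)]
        z0, _ = perturb_params(surf.params, 0.1, seed=3)
        ledger = staged_fit(specs, surf.params.bounds, z0.values, n_starts=6,
                            global_evals=1000, local_evals=500, seed=0)
        assert (ledger.records[1]["best_chi"]
                <= ledger.records[0]["best_chi"] + 1e-12)

    def test_three_stage_recovery_improves_validation_rmse(self):
        ledger, z0, err, specs = recovery_experiment(0, 100, 0)
        # held-out check: final-stage parameters beat first-stage on the
        # largest dataset
        z1 = np.asarray(ledger.records[0]["best_zeta"])
        zf = ledger.best_zeta
        assert energy_rmse(zf, specs[-1]) <= energy_rmse(z1, specs[-1]) + 1e-9
        assert err < 0.02

    def test_empty_stage_list_rejected(self):
        with pytest.raises(ValueError):
            staged_fit([], np.array([[0.0, 1.0]]), np.array([0.5]))


class TestCumulativeRmse:
    def _spec(self, toy3):
        surf, _ = toy3
        g0 = surf.relaxed_chain(0.0)
        rng = np.random.default_rng(2)
        geoms = g0 + rng.uniform(-0.1, 0.1, size=(30, 3))
        e0 = surf.energy(g0)
        ds = ReferenceDataset([RefEntry(g, energy=surf.energy(g) - e0, tag="core")
                               for g in geoms])
        return surf, g0, ds

    def test_perfect_fit_zero_curve(self, toy3):
        surf, g0, ds = self._spec(toy3)
        curve = cumulative_rmse(ds, surf, surf.params.values,
                                [1e3, 1e4, 1e6], g0)
        assert all(c["rmse"] == pytest.approx(0.0, abs=1e-10)
                   for c in curve if c["rmse"] is not None)

    def test_single_cutoff_above_max_is_global_rmse(self, toy3):
        surf, g0, ds = self._spec(toy3)
        z0, _ = perturb_params(surf.params, 0.1, seed=5)
        curve = cumulative_rmse(ds, surf, z0.values, [1e9], g0)
        spec = ObjectiveSpec(ds, surf, g0)
        assert curve[0]["rmse"] == pytest.approx(energy_rmse(z0.values, spec))

    def test_empty_bin_flagged(self, toy3):
        surf, g0, ds = self._spec(toy3)
        curve = cumulative_rmse(ds, surf, surf.params.values, [-10.0, 1e9], g0)
        assert curve[0]["flag"] == "empty bin"
        assert curve[1]["n"] == 30

    def test_descending_cutoffs_rejected(self, toy3):
        surf, g0, ds = self._spec(toy3)
        with pytest.raises(ValueError):
            cumulative_rmse(ds, surf, surf.params.values, [2.0, 1.0], g0)
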