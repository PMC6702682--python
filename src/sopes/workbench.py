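"""Pipeline orchestration, configuration, reporting and the ``sopes`` CLI.

``run_pipeline`` executes the full workflow on a toy backend: build the
staged reference sets around the stationary points, refit the surface
parameters from a perturbed start, tensor-decompose the fitted surface with
Multigrid POTFIT, and (for <= 3 DOFs) diagonalize the decomposed potential
and compare the eigenlevels of the fitted and the starting surface against
the reference.  Every random operation is seeded from the config and the
config hash is embedded in all outputs, so identical configs give
bit-identical ledgers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from sopes import decompose as dec
from sopes import eigensolve as eig
from sopes import refset, srp_opt
from sopes.grids import build_dvr, make_multigrid
from sopes.sop_tensor import read_sop, write_sop
from sopes.stationary_vib import PointKind, refine_stationary
from sopes.surfaces import ToyTorsionSurface, perturb_params, toy_reference

__all__ = ["SchemaError", "validate_config", "run_pipeline", "report",
           "compare_on_trajectory", "main"]


class SchemaError(ValueError):
    """Configuration failed schema validation; names the offending field."""


_REQUIRED = ["backend", "grids", "stages", "optimizer", "stride", "seed", "outdir"]


def validate_config(config: dict) -> dict:
    """Check the pipeline config for required blocks; returns it unchanged."""
    for key in _REQUIRED:
        if key not in config:
            raise SchemaError(f"missing required config field '{key}'")
    if config["backend"].get("type", "toy") not in ("toy",):
        raise SchemaError("backend.type must be 'toy' (external backends run "
                          "through the library API)")
    for i, g in enumerate(config["grids"]):
        for field in ("kind", "n", "first", "last"):
            if field not in g:
                raise SchemaError(f"grids[{i}] missing field '{field}'")
    return config


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def _build_stages(surface, sps, config, e0):
    """Stage datasets per the config's class lists."""
    bounds = surface.coordinate_bounds()
    seed = int(config["seed"])
    min1, min2, ts = sps
    components_by_class = {}
    f = surface.dof_count
    # displacements scaled to a chemically relevant energy window
    # (~e_disp cm^-1 along each chain coordinate, fixed arc on the torsion)
    e_disp = config.get("displacement_energy", 3000.0)
    diag = np.diag(min1.hessian)
    deltas = np.append(np.sqrt(2.0 * e_disp / diag[:-1]), 0.8)
    core = refset.ReferenceDataset(
        [refset.RefEntry(sp.geometry, tag="core") for sp in sps])
    n_cloud = config["stages"][0].get("n_core_cloud", 15)
    clouds = [refset.random_fD(
        np.column_stack([sp.geometry - deltas, sp.geometry + deltas]),
        n_cloud, seed + 10 + i, tag="core") for i, sp in enumerate(sps)]
    components_by_class["core"] = [core, *clouds]
    components_by_class["1D"] = [
        refset.grid_displacements(sp, 1, list(range(f)), deltas,
                                  config.get("n_per_dof", 4)) for sp in sps]
    components_by_class["2D"] = [
        refset.grid_displacements(sp, 2, list(range(f)), deltas,
                                  config.get("n_per_pair", 3)) for sp in sps]
    components_by_class["rnd(fD)"] = [
        refset.random_fD(bounds, config.get("n_random", 20), seed + 1)]
    path1 = refset.liic(min1, ts, config.get("liic_points", 12),
                        periodic=surface.periodic)
    path2 = refset.liic(ts, min2, config.get("liic_points", 12),
                        periodic=surface.periodic)
    components_by_class["LIIC"] = [refset.path_dataset(p) for p in (path1, path2)]
    components_by_class["rnd(LIIC)"] = [
        refset.liic_cloud(path1, min1.modes, ts.modes,
                          config.get("cloud_per_point", 1), 0.1, seed + 2,
                          exclude_mode=None)]
    stages, ledger_rows, ids = [], [], set()
    for i, spec in enumerate(config["stages"]):
        comps = []
        for cls in spec["classes"]:
            comps.extend(components_by_class[cls])
        ds, row = refset.assemble_stage(spec.get("id", f"stage{i + 1}"), comps,
                                        existing_ids=ids)
        ids.add(row["stage"])
        stages.append(ds.with_energies(surface, reference_energy=e0))
        ledger_rows.append(row)
    return stages, ledger_rows


def run_pipeline(config: dict) -> Path:
    """Run refset -> srp_opt -> decompose -> eigensolve; returns the run directory."""
    config = validate_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    seed = int(config["seed"])

    # backend and ground truth
    bspec = config["backend"]
    surface, meta = toy_reference(bspec.get("seed", 0), f=bspec.get("f", 3))
    zeta_star = surface.params.values
    zeta0, pert_report = perturb_params(surface.params,
                                        bspec.get("perturbation", 0.2),
                                        bspec.get("perturbation_seed", seed))

    # reference stationary points and staged datasets
    min1 = refine_stationary(surface, None, surface.relaxed_chain(0.0), PointKind.MINIMUM)
    min2 = refine_stationary(surface, None, surface.relaxed_chain(np.pi), PointKind.MINIMUM)
    ts = refine_stationary(surface, None, surface.ts_guess(), PointKind.TS)
    e0 = min(min1.energy, min2.energy)
    ref_geom = min1.geometry if min1.energy <= min2.energy else min2.geometry
    stage_data, stage_ledger = _build_stages(surface, (min1, min2, ts), config, e0)

    # staged refit from the perturbed start
    opt = config["optimizer"]
    specs = [srp_opt.ObjectiveSpec(ds, surface, ref_geom,
                                   form=opt.get("form", "chi1"))
             for ds in stage_data]
    fit = srp_opt.staged_fit(specs, surface.params.bounds, zeta0.values,
                             n_starts=opt.get("n_starts", 12),
                             global_evals=opt.get("global_evals", 3000),
                             local_evals=opt.get("local_evals", 1500),
                             seed=seed)
    zeta_hat = fit.best_zeta

    # MGPF decomposition of the fitted surface on the configured grid
    grids = [build_dvr(g["kind"], g["n"], (g["first"], g["last"]),
                       name=g.get("name", "")) for g in config["grids"]]
    mg = make_multigrid(grids, int(config["stride"]))
    points = [g.points for g in grids]

    def backend_on_grid(idx, _z=zeta_hat):
        geom = np.array([points[k][i] for k, i in enumerate(idx)])
        return surface.energy(geom, _z) - surface.energy(ref_geom, _z)

    mgpf = dec.mgpf_decompose(backend_on_grid, mg)
    mgpf.potential.meta.update({"config_hash": chash, "energy_units": "cm-1"})
    write_sop(mgpf.potential, outdir / "pes.sop")

    # eigensolve and start-vs-fitted comparison (<= 3D only)
    eigen_block = None
    if len(grids) <= 3:
        k = config.get("eigensolve", {}).get("k", 6)
        masses = np.ones(len(grids))

        def grid_values(zeta):
            mesh = np.meshgrid(*points, indexing="ij")
            geoms = np.column_stack([m.ravel() for m in mesh])
            rel = surface.energy_many(geoms, zeta) - surface.energy(ref_geom, zeta)
            return rel.reshape([g.n_points for g in grids])

        rep_ref = eig.lowest_eigenpairs(
            eig.build_hamiltonian(grids, masses, grid_values(None)), k)
        rep_fit = eig.lowest_eigenpairs(
            eig.build_hamiltonian(grids, masses, mgpf.potential), k)
        rep_start = eig.lowest_eigenpairs(
            eig.build_hamiltonian(grids, masses, grid_values(zeta0.values)), k)
        rmse_fit, mad_fit = eig.eigen_rmse(rep_fit.levels, rep_ref.levels)
        rmse_start, mad_start = eig.eigen_rmse(rep_start.levels, rep_ref.levels)
        rep_fit.to_csv(outdir / "levels.csv")
        eigen_block = {
            "k": k,
            "levels_reference": rep_ref.levels.tolist(),
            "levels_fitted": rep_fit.levels.tolist(),
            "levels_start": rep_start.levels.tolist(),
            "zpe_reference": rep_ref.zpe,
            "zpe_fitted": rep_fit.zpe,
            "eigen_rmse_fitted": rmse_fit,
            "eigen_rmse_start": rmse_start,
            "eigen_mad_fitted": mad_fit,
            "eigen_mad_start": mad_start,
        }

    summary = {
        "config_hash": chash,
        "backend_meta": meta,
        "zeta_star": zeta_star.tolist(),
        "zeta_start": zeta0.values.tolist(),
        "zeta_fitted": zeta_hat.tolist(),
        "start_percent_deviation": pert_report["percent_deviation"],
        "relative_param_error_start": float(
            np.linalg.norm(zeta0.values - zeta_star) / np.linalg.norm(zeta_star)),
        "relative_param_error_fitted": float(
            np.linalg.norm(zeta_hat - zeta_star) / np.linalg.norm(zeta_star)),
        "stage_ledger": stage_ledger,
        "mgpf": {"n_calls": mgpf.n_calls, "stride": int(config["stride"]),
                 "rmse_report": mgpf.rmse_report},
        "eigensolve": eigen_block,
    }
    (outdir / "ledger.json").write_text(
        json.dumps({"config_hash": chash, **fit.to_json_dict()}, indent=2,
                   sort_keys=True))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    return outdir


def compare_on_trajectory(backend, trajectory, zetas: dict,
                          reference_geometry) -> dict:
    """Re-evaluate a trajectory's geometries under alternative parameters.

    Returns, per parameter-set label, the RMSE of the re-evaluated relative
    energies against the trajectory's own potential energies (its surface is
    the reference).
    """
    geoms = trajectory.geometries()
    e_ref = trajectory.energies()[:, 0]
    e_ref = e_ref - e_ref.min()
    out = {}
    for label, zeta in zetas.items():
        e0 = backend.energy(reference_geometry, zeta)
        e = backend.energy_many(geoms, zeta) - e0
        out[label] = float(np.sqrt(np.mean((e - e.min() - e_ref) ** 2)))
    return out


def report(run_dir) -> str:
    """Human-readable summary of a completed run directory."""
    run_dir = Path(run_dir)
    sections = []
    missing = []
    summary = None
    if (run_dir / "summary.json").exists():
        summary = json.loads((run_dir / "summary.json").read_text())
    else:
        missing.append("summary.json")
    if (run_dir / "ledger.json").exists():
        ledger = json.loads((run_dir / "ledger.json").read_text())
        lines = ["Stage ledger:",
                 f"{'stage':<10}{'points':>8}{'optimizer':>16}{'chi':>14}{'RMSE':>12}"]
        for rec in ledger["stages"]:
            lines.append(f"{rec['stage']:<10}{rec['n_points']:>8}"
                         f"{rec['optimizer']:>16}{rec['best_chi']:>14.4g}"
                         f"{rec['rmse']:>12.4g}")
        sections.append("\n".join(lines))
    else:
        missing.append("ledger.json")
    if summary:
        dev = summary["start_percent_deviation"]
        lines = ["Parameter deviation of the start from truth (%):"]
        lines += [f"  {k:<8}{v:>10.2f}" for k, v in dev.items()]
        lines.append(f"relative parameter error: start "
                     f"{summary['relative_param_error_start']:.4f} -> fitted "
                     f"{summary['relative_param_error_fitted']:.4f}")
        sections.append("\n".join(lines))
        mg = summary["mgpf"]
        sections.append(
            f"MGPF: stride {mg['stride']}, {mg['n_calls']} backend calls, "
            f"sampled RMSE {mg['rmse_report']['rmse']:.4g} cm-1")
        if summary.get("eigensolve"):
            e = summary["eigensolve"]
            sections.append(
                "Eigenlevel comparison vs reference surface (cm-1):\n"
                f"  start  RMSE {e['eigen_rmse_start']:.2f}  MAD {e['eigen_mad_start']:.2f}\n"
                f"  fitted RMSE {e['eigen_rmse_fitted']:.2f}  MAD {e['eigen_mad_fitted']:.2f}")
        else:
            sections.append("Eigenlevel comparison: absent (run had > 3 DOFs)")
    if missing:
        sections.append("Missing artifacts: " + ", ".join(missing))
    return "\n\n".join(sections)


# ---------------------------------------------------------------------------
# CLI

import click  # noqa: E402


@click.group()
def cli():
    """Sum-of-products PES toolkit."""


@cli.command("run")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
def run_cmd(config_path):
    """Run the full pipeline from a YAML config."""
    config = yaml.safe_load(Path(config_path).read_text())
    outdir = run_pipeline(config)
    click.echo(f"run complete: {outdir}")


@cli.command("report")
@click.argument("run_dir", type=click.Path(exists=True))
def report_cmd(run_dir):
    """Summarize a completed run directory."""
    click.echo(report(run_dir))


@cli.command("decompose")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--stride", default=3, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--backend-seed", default=0, show_default=True)
def decompose_cmd(config_path, stride, out_path, backend_seed):
    """MGPF-decompose the toy backend on the configured grids."""
    cfg = yaml.safe_load(Path(config_path).read_text())
    grids = [build_dvr(g["kind"], g["n"], (g["first"], g["last"]),
                       name=g.get("name", "")) for g in cfg["grids"]]
    surface, _ = toy_reference(backend_seed, f=len(grids))
    points = [g.points for g in grids]

    def backend(idx):
        return surface.energy(np.array([points[k][i] for k, i in enumerate(idx)]))

    result = dec.mgpf_decompose(backend, make_multigrid(grids, stride))
    write_sop(result.potential, out_path)
    click.echo(f"{result.n_calls} backend calls; sampled RMSE "
               f"{result.rmse_report['rmse']:.4g}; wrote {out_path}")


@cli.command("eigensolve")
@click.option("--sop", "sop_path", required=True, type=click.Path(exists=True))
@click.option("--k", default=10, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def eigensolve_cmd(sop_path, k, out_path):
    """Diagonalize a (<= 3D) SOP potential and write the level list."""
    pot = read_sop(sop_path)
    ham = eig.build_hamiltonian(pot.grids, np.ones(pot.f), pot)
    rep = eig.lowest_eigenpairs(ham, k)
    rep.to_csv(out_path)
    click.echo(f"ZPE {rep.zpe:.4f} cm-1; wrote {out_path}")


def main():
    cli()


if __name__ == "__main__":
    main()
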