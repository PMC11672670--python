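"""End-to-end orchestration: points -> modes -> displace/restrain -> analyze.

``run_pipeline`` executes the in-scope stages of the sampling workflow on a
toy structure or a user PDB and persists every intermediate artifact (CSV,
mode matrix, multi-model PDB) together with the resolved configuration and
a log of seeds and versions, so any run can be reproduced from its output
directory alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dpvac import HarmonicENMModel, NullModel, RestraintSpec, energy_surface, generate_path
from .errors import NMSphereError
from .hypersphere import MinimizationConfig, init_points, minimize, minimize_mirrored
from .io import RunConfig, make_toy_structure, read_pdb, write_pdb
from .modes import build_enm_hessian, compute_modes, save_modes
from .nmspace import Ensemble, combine, displace_pointset, project_ensemble
from .analysis import radius_of_gyration, rmsf

logger = logging.getLogger("nmsphere")

__all__ = ["run_pipeline"]


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise NMSphereError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorator


def run_pipeline(cfg: RunConfig, outdir) -> Path:
    """Run every in-scope stage and return the artifact directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    old_level = logger.level
    logger.setLevel(logging.INFO)
    try:
        logger.info("nmsphere %s | seed=%d | numpy=%s", __version__, cfg.seed, np.__version__)
        ps = _points_stage(cfg, out)
        st = _structure_stage(cfg, out)
        ms = _modes_stage(cfg, st, out)
        ens = _displace_stage(cfg, ps, st, ms, out)
        paths = _dpvac_stage(cfg, ps, st, ms, out)
        _project_stage(cfg, ens, st, ms, paths, out)
        _analysis_stage(cfg, ens, st, out)
    finally:
        logger.removeHandler(handler)
        handler.close()
        logger.setLevel(old_level)
    return out


@_stage("points")
def _points_stage(cfg: RunConfig, out: Path):
    mcfg = MinimizationConfig(
        alpha=cfg.alpha, grad_tol=cfg.grad_tol, max_cycles=cfg.max_cycles,
        seed=cfg.seed, mirrored=cfg.mirrored,
    )
    if cfg.mirrored:
        from .hypersphere import kissing_preset

        n = cfg.n_points if cfg.n_points is not None else kissing_preset(cfg.dim)
        if n % 2:
            raise NMSphereError(f"mirrored minimization needs an even point count, got {n}")
        ps, trace = minimize_mirrored(n // 2, cfg.dim, mcfg, restarts=cfg.restarts)
    else:
        from .hypersphere import kissing_preset

        n = cfg.n_points if cfg.n_points is not None else kissing_preset(cfg.dim)
        ps, trace = minimize(init_points(n, cfg.dim, cfg.seed), mcfg, restarts=cfg.restarts)
    ps.to_csv(out / "points.csv")
    trace.to_csv(out / "trace.csv")
    logger.info("points: n=%d dim=%d final Mdist=%.6f", ps.n, ps.dim, trace.final_mdist)
    return ps


@_stage("structure")
def _structure_stage(cfg: RunConfig, out: Path):
    if cfg.pdb is not None:
        st = read_pdb(cfg.pdb)
        if isinstance(st, Ensemble):
            st = st.structure
    else:
        st = make_toy_structure(
            cfg.toy_atoms, kind=cfg.toy_kind, seed=cfg.seed, mass_pattern=cfg.toy_mass_pattern
        )
    write_pdb(st, out / "reference.pdb")
    return st


@_stage("modes")
def _modes_stage(cfg: RunConfig, st, out: Path):
    hess = build_enm_hessian(st, cutoff=cfg.cutoff, gamma=cfg.gamma)
    ms = compute_modes(hess, st.masses, k=cfg.dim)
    save_modes(ms, out / "modes.txt")
    return ms


@_stage("displace")
def _displace_stage(cfg: RunConfig, ps, st, ms, out: Path):
    ens = displace_pointset(ps, st, ms, amplitude=cfg.amplitude, metric=cfg.metric)
    write_pdb(ens, out / "ensemble.pdb")
    return ens


@_stage("dpvac")
def _dpvac_stage(cfg: RunConfig, ps, st, ms, out: Path):
    spec = RestraintSpec(k_mod=cfg.k_mod, step=cfg.step, d_max=cfg.d_max)
    if cfg.model == "null":
        model = NullModel()
    elif cfg.model == "enm":
        model = HarmonicENMModel(st, build_enm_hessian(st, cutoff=cfg.cutoff, gamma=cfg.gamma))
    else:
        raise NMSphereError(f"unknown energy model {cfg.model!r}")
    paths = []
    frames = []
    for i, point in enumerate(ps.points):
        cv = combine(ms, point)
        path = generate_path(st, cv, spec, model, vector_index=i)
        paths.append(path)
        frames.append(path.to_frame())
    pd.concat(frames, ignore_index=True).to_csv(out / "paths.csv", index=False)
    for path in paths:
        write_pdb(path.to_ensemble(st), out / f"path_{path.vector_index:03d}.pdb")
    return paths


@_stage("project")
def _project_stage(cfg: RunConfig, ens, st, ms, paths, out: Path):
    proj = project_ensemble(ens, st, ms, axes=cfg.axes)
    proj.to_csv(out / "projections.csv", index=False)
    if len(paths) >= 3:
        surf = energy_surface(paths, st, ms, axes=cfg.axes)
        surf.to_csv(out / "surface.csv")


@_stage("analyze")
def _analysis_stage(cfg: RunConfig, ens, st, out: Path):
    rg = pd.DataFrame(
        {
            "model": np.arange(1, len(ens) + 1),
            "rgyr": [radius_of_gyration(ens[i], st.masses) for i in range(len(ens))],
        }
    )
    rg.to_csv(out / "rgyr.csv", index=False)
    rmsf(ens).to_csv(out / "rmsf.csv", index=False)
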