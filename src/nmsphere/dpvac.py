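"""Restrained structure generation along combined normal-mode vectors.

A structure is driven to equidistant mass-weighted displacements along a
combination vector by minimizing

    f(x) = U(x) + k_mod * (d(x) - d_r)**2

where ``U`` is a pluggable model energy, ``d(x)`` is the signed MRMSD
projection of ``x - ref`` onto the vector, and ``d_r`` walks from ``step``
to ``d_max`` in increments of ``step`` (defaults 0.1 Å and 3.0 Å, i.e. 30
structures per vector).  Each step is warm-started from the previous one.
The restraint penalizes only the projection along the vector; an optional
quadratic penalty on the orthogonal drift is available but off by default.

Shipped model energies: a null model (restraint-only dynamics, useful for
exact checks) and a harmonic elastic-network model about the reference,
U = 1/2 dx^T H dx with H the ENM Hessian.  Collecting the per-step
restraint energies from many paths and interpolating them on the plane of
two modes yields a restraining-energy surface: the energetic cost of
holding the conformation at each position of the mode plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from scipy.optimize import minimize as scipy_minimize

from .errors import InvalidArgumentError
from .modes import ModeSet, Structure
from .nmspace import CombinationVector, Ensemble, mrmsd_projection

logger = logging.getLogger("nmsphere")

__all__ = [
    "RestraintSpec",
    "PathRecord",
    "DisplacementPath",
    "EnergySurface",
    "EnergyModel",
    "NullModel",
    "HarmonicENMModel",
    "restraint_energy",
    "vmod_step",
    "generate_path",
    "energy_surface",
]


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic restraint settings: force constant and the displacement ladder."""

    k_mod: float = 1.0e4  # kcal/mol/Å²
    step: float = 0.1  # Å
    d_max: float = 3.0  # Å

    def __post_init__(self) -> None:
        if self.k_mod <= 0:
            raise InvalidArgumentError("k_mod must be positive")
        if not 0.0 < self.step <= self.d_max:
            raise InvalidArgumentError("need 0 < step <= d_max")

    def targets(self) -> np.ndarray:
        n = int(round(self.d_max / self.step))
        return np.arange(1, n + 1) * self.step


class EnergyModel(Protocol):
    """Differentiable model energy over flat coordinates (3 N,)."""

    def energy(self, x: np.ndarray) -> float: ...

    def gradient(self, x: np.ndarray) -> np.ndarray: ...


class NullModel:
    """Zero energy everywhere; the restraint alone shapes the optimum."""

    def energy(self, x: np.ndarray) -> float:
        return 0.0

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return np.zeros_like(x)


class HarmonicENMModel:
    """Quadratic model about the reference: U = 1/2 dx^T H dx (kcal/mol).

    ``hessian`` is the Cartesian ENM Hessian evaluated at the reference
    coordinates, so the model is convex and exact closed forms exist for
    every restrained optimum.
    """

    def __init__(self, ref: Structure, hessian: np.ndarray):
        self.ref_flat = ref.coords.ravel().copy()
        self.hessian = np.asarray(hessian, dtype=float)
        if self.hessian.shape != (self.ref_flat.size, self.ref_flat.size):
            raise InvalidArgumentError("hessian size does not match the reference")

    def energy(self, x: np.ndarray) -> float:
        dx = x - self.ref_flat
        return float(0.5 * dx @ self.hessian @ dx)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.hessian @ (x - self.ref_flat)


def restraint_energy(d: float, k_mod: float, d_r: float) -> float:
    """Harmonic restraint k_mod * (d - d_r)**2 in kcal/mol (no 1/2 prefactor)."""
    if k_mod <= 0:
        raise InvalidArgumentError("k_mod must be positive")
    return float(k_mod * (d - d_r) ** 2)


@dataclass
class PathRecord:
    """One restrained minimization outcome along a path."""

    d_target: float
    d_achieved: float
    e_restraint: float
    e_model: float
    coords: np.ndarray
    converged: bool = True
    grad_norm: float = 0.0

    @property
    def e_total(self) -> float:
        return self.e_model + self.e_restraint


@dataclass
class DisplacementPath:
    """Restrained structures at equidistant MRMSDs along one vector."""

    vector_index: int
    cv: CombinationVector
    records: list[PathRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vector": self.vector_index,
                "step": np.arange(1, len(self.records) + 1),
                "d_target": [r.d_target for r in self.records],
                "d_achieved": [r.d_achieved for r in self.records],
                "e_restraint": [r.e_restraint for r in self.records],
                "e_model": [r.e_model for r in self.records],
            }
        )

    def to_ensemble(self, ref: Structure) -> Ensemble:
        coords = np.stack([r.coords.reshape(-1, 3) for r in self.records])
        tags = [
            {"vector": self.vector_index, "step": i + 1, "stage": "dpvac"}
            for i in range(len(self.records))
        ]
        return Ensemble(structure=ref, coords=coords, tags=tags)


def vmod_step(
    conf: np.ndarray,
    ref: Structure,
    cv: CombinationVector,
    d_r: float,
    k_mod: float,
    model: EnergyModel,
    grad_tol: float = 1e-6,
    max_iter: int = 2000,
    k_orth: float = 0.0,
) -> PathRecord:
    """Minimize model + restraint starting from ``conf``; return the record.

    ``d(x)`` is the signed projection of ``x - ref`` onto the combination
    vector in the mass-weighted metric.  The minimization itself runs in
    mass-weighted coordinates, so with a null model the optimizer moves
    purely along the combination vector.  ``k_orth > 0`` additionally
    penalizes the squared mass-weighted displacement orthogonal to the
    vector (off by default).
    """
    if d_r < 0:
        raise InvalidArgumentError("d_r must be >= 0")
    w = ref.mass_weights()
    q = cv.mw_vector
    ref_flat = ref.coords.ravel()

    def objective(y: np.ndarray) -> tuple[float, np.ndarray]:
        x = ref_flat + y / w
        d = float(y @ q)
        f = model.energy(x) + k_mod * (d - d_r) ** 2
        g = model.gradient(x) / w + 2.0 * k_mod * (d - d_r) * q
        if k_orth > 0.0:
            orth = y - d * q
            f += k_orth * float(orth @ orth)
            g += 2.0 * k_orth * (orth - (orth @ q) * q)
        return f, g

    y0 = (np.asarray(conf, dtype=float).ravel() - ref_flat) * w
    res = scipy_minimize(
        objective,
        y0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": grad_tol, "ftol": 1e-15},
    )
    x = ref_flat + res.x / w
    d = float(res.x @ q)
    grad_norm = float(np.max(np.abs(objective(res.x)[1])))
    converged = bool(res.success) or grad_norm <= 10 * grad_tol
    if not converged:
        logger.warning(
            "vmod step at d_r=%.3f did not converge (max |grad| %.3g)", d_r, grad_norm
        )
    return PathRecord(
        d_target=d_r,
        d_achieved=d,
        e_restraint=restraint_energy(d, k_mod, d_r),
        e_model=model.energy(x),
        coords=x,
        converged=converged,
        grad_norm=grad_norm,
    )


def generate_path(
    ref: Structure,
    cv: CombinationVector,
    spec: RestraintSpec,
    model: EnergyModel,
    vector_index: int = 0,
    **step_kwargs,
) -> DisplacementPath:
    """Walk the restraint ladder, warm-starting each step from the last."""
    path = DisplacementPath(vector_index=vector_index, cv=cv)
    x = ref.coords.ravel().copy()
    for d_r in spec.targets():
        rec = vmod_step(x, ref, cv, float(d_r), spec.k_mod, model, **step_kwargs)
        logger.info(
            "vmod vector=%d d_r=%.2f achieved=%.4f e_model=%.4g e_restraint=%.4g",
            vector_index, d_r, rec.d_achieved, rec.e_model, rec.e_restraint,
        )
        path.records.append(rec)
        x = rec.coords
    return path


@dataclass
class EnergySurface:
    """Restraining energy interpolated on a regular grid of a mode plane.

    ``values`` is indexed [iy, ix]; cells outside the convex hull of the
    sampled projections are NaN (undefined).
    """

    axes: tuple[int, int]
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    samples: pd.DataFrame

    def to_csv(self, path) -> None:
        xx, yy = np.meshgrid(self.x, self.y)
        pd.DataFrame(
            {
                f"mode_{self.axes[0]}": xx.ravel(),
                f"mode_{self.axes[1]}": yy.ravel(),
                "energy": self.values.ravel(),
            }
        ).to_csv(path, index=False)


def energy_surface(
    paths: list[DisplacementPath],
    ref: Structure,
    ms: ModeSet,
    axes: tuple[int, int] = (7, 8),
    grid: int = 61,
    include_origin: bool = True,
) -> EnergySurface:
    """Interpolate per-step restraint energies onto the plane of two modes."""
    if len(paths) < 3:
        raise InvalidArgumentError("need at least three paths to span a plane")
    a, b = axes
    pts = []
    vals = []
    if include_origin:
        pts.append((0.0, 0.0))
        vals.append(0.0)
    for path in paths:
        for rec in path.records:
            conf = rec.coords.reshape(-1, 3)
            pts.append(
                (mrmsd_projection(conf, ref, ms, a), mrmsd_projection(conf, ref, ms, b))
            )
            vals.append(rec.e_restraint)
    pts_arr = np.asarray(pts)
    vals_arr = np.asarray(vals)
    centered = pts_arr - pts_arr.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise InvalidArgumentError("path projections are collinear; no plane to interpolate")
    x = np.linspace(pts_arr[:, 0].min(), pts_arr[:, 0].max(), grid)
    y = np.linspace(pts_arr[:, 1].min(), pts_arr[:, 1].max(), grid)
    xx, yy = np.meshgrid(x, y)
    zz = griddata(pts_arr, vals_arr, (xx, yy), method="linear")
    samples = pd.DataFrame(
        {f"mode_{a}": pts_arr[:, 0], f"mode_{b}": pts_arr[:, 1], "energy": vals_arr}
    )
    return EnergySurface(axes=axes, x=x, y=y, values=zz, samples=samples)
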