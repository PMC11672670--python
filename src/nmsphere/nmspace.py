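"""Mapping hypersphere points to normal-mode displacements and back.

Each point on a D-dimensional unit hypersphere supplies D weights for a
linear combination of D orthonormal mass-weighted modes.  Displacing the
reference structure by an amplitude ``a`` (measured as mass-weighted RMSD,
MRMSD) along every combination vector turns the point set into a
conformational ensemble, and because the modes are orthonormal in the
mass-weighted metric the map is an exact isometry: pairwise MRMSDs between
conformations equal ``a`` times the pairwise Euclidean distances between
the hypersphere points.

The signed projection of a conformation onto mode ``j``,

    d_j = sum_{i,alpha} sqrt(m_i / M) (r_i,alpha - r^ref_i,alpha) q_i,alpha,j

is the scalar product between the mass-weighted displacement and the unit
mode vector; it recovers the displacement amplitude along that mode in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .errors import InvalidArgumentError, TopologyError
from .hypersphere import PointSet
from .modes import ModeSet, Structure

__all__ = [
    "CombinationVector",
    "Ensemble",
    "CorrespondenceReport",
    "combine",
    "displace",
    "displace_pointset",
    "mrmsd",
    "plain_rmsd",
    "mrmsd_projection",
    "project_ensemble",
    "correspondence_report",
]


@dataclass
class CombinationVector:
    """A unit-norm linear combination of normal modes.

    ``weights`` are the hypersphere point coordinates; ``mw_vector`` is the
    combined mode in mass-weighted coordinates (unit norm); ``cartesian`` is
    the Cartesian displacement in Å per 1 Å of MRMSD amplitude.
    """

    weights: np.ndarray
    mw_vector: np.ndarray
    cartesian: np.ndarray
    labels: np.ndarray

    @property
    def dim(self) -> int:
        return self.weights.shape[0]


@dataclass
class Ensemble:
    """Ordered conformations sharing one Structure topology."""

    structure: Structure
    coords: np.ndarray  # (n_models, n_atoms, 3)
    tags: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.structure.n_atoms, 3):
            raise TopologyError(
                f"ensemble coordinates of shape {self.coords.shape} do not match "
                f"the {self.structure.n_atoms}-atom topology"
            )
        if not self.tags:
            self.tags = [{} for _ in range(len(self))]

    def __len__(self) -> int:
        return self.coords.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.coords[i]


def combine(ms: ModeSet, weights) -> CombinationVector:
    """Weight the modes of ``ms`` into a single unit combination vector."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (ms.k,):
        raise InvalidArgumentError(
            f"expected {ms.k} weights (one per mode), got shape {w.shape}"
        )
    norm = np.linalg.norm(w)
    if norm == 0.0:
        raise InvalidArgumentError("weights must not all be zero")
    w = w / norm
    mw = w @ ms.vectors
    weight_per_coord = np.repeat(np.sqrt(ms.masses / ms.masses.sum()), 3)
    cart = mw / weight_per_coord
    return CombinationVector(weights=w, mw_vector=mw, cartesian=cart, labels=ms.labels.copy())


def mrmsd(conf: np.ndarray, ref: np.ndarray, masses) -> float:
    """Mass-weighted RMSD, no superposition: sqrt(sum m |dr|^2 / M)."""
    masses = np.asarray(masses, dtype=float)
    d2 = np.sum((np.asarray(conf) - np.asarray(ref)) ** 2, axis=1)
    return float(np.sqrt(np.sum(masses * d2) / masses.sum()))


def plain_rmsd(conf: np.ndarray, ref: np.ndarray) -> float:
    """Unweighted all-atom RMSD, no superposition."""
    d2 = np.sum((np.asarray(conf) - np.asarray(ref)) ** 2, axis=1)
    return float(np.sqrt(np.mean(d2)))


def displace(
    st: Structure,
    cv: CombinationVector,
    amplitude: float = 1.0,
    metric: str = "mass",
) -> np.ndarray:
    """Displace ``st`` along ``cv`` so the displacement measures ``amplitude`` Å.

    ``metric='mass'`` measures the amplitude as MRMSD; ``metric='plain'`` as
    unweighted RMSD.  For uniform masses the two coincide.
    """
    if amplitude < 0:
        raise InvalidArgumentError("amplitude must be >= 0")
    step = cv.cartesian.reshape(-1, 3)
    if metric == "mass":
        scale = 1.0
    elif metric == "plain":
        scale = 1.0 / np.sqrt(np.mean(np.sum(step**2, axis=1)))
    else:
        raise InvalidArgumentError(f"metric must be 'mass' or 'plain', got {metric!r}")
    return st.coords + amplitude * scale * step


def displace_pointset(
    ps: PointSet,
    st: Structure,
    ms: ModeSet,
    amplitude: float = 1.0,
    metric: str = "mass",
) -> Ensemble:
    """One conformation per hypersphere point, displaced ``amplitude`` Å."""
    if ps.dim != ms.k:
        raise InvalidArgumentError(
            f"point dimension {ps.dim} does not match mode count {ms.k}"
        )
    confs = []
    tags = []
    for i, point in enumerate(ps.points):
        cv = combine(ms, point)
        confs.append(displace(st, cv, amplitude=amplitude, metric=metric))
        tags.append({"vector": i, "amplitude": amplitude, "stage": "displace"})
    return Ensemble(structure=st, coords=np.stack(confs), tags=tags)


def mrmsd_projection(conf: np.ndarray, ref: Structure, ms: ModeSet, label: int) -> float:
    """Signed MRMSD projection of ``conf`` onto the mode labeled ``label``."""
    conf = np.asarray(conf, dtype=float)
    if conf.shape != ref.coords.shape:
        raise TopologyError(
            f"conformation shape {conf.shape} does not match reference "
            f"shape {ref.coords.shape}"
        )
    q = ms.vector_for(label)
    delta = (conf - ref.coords).ravel() * ref.mass_weights()
    return float(delta @ q)


def project_ensemble(
    ens: Ensemble, ref: Structure, ms: ModeSet, axes: tuple[int, int] = (7, 8)
) -> pd.DataFrame:
    """Map every conformation onto the plane of two modes (one row per model)."""
    a, b = axes
    rows = [
        {
            "model": i + 1,
            f"mode_{a}": mrmsd_projection(ens[i], ref, ms, a),
            f"mode_{b}": mrmsd_projection(ens[i], ref, ms, b),
        }
        for i in range(len(ens))
    ]
    return pd.DataFrame(rows)


class CorrespondenceReport(NamedTuple):
    min_rmsd: float
    max_abs_diff: float
    pearson_r: float


def correspondence_report(
    ps: PointSet,
    ens: Ensemble,
    ref: Structure,
    metric: str = "mass",
    amplitude: float = 1.0,
) -> CorrespondenceReport:
    """Quantify hypersphere <-> conformation-space agreement.

    ``ens`` must hold one conformation per point of ``ps`` (displaced
    ``amplitude`` Å from ``ref``).  Returns the minimal pairwise
    conformation distance, the largest absolute difference between scaled
    hypersphere distances and conformation distances, and their Pearson
    correlation.
    """
    if ps.n < 2:
        raise InvalidArgumentError("need at least two points for a correspondence report")
    if len(ens) != ps.n:
        raise InvalidArgumentError(
            f"ensemble has {len(ens)} models but the point set has {ps.n} points"
        )
    sphere_d = pdist(ps.points) * amplitude
    if metric == "mass":
        w = np.sqrt(ref.masses / ref.total_mass)
        flat = (ens.coords * w[None, :, None]).reshape(len(ens), -1)
        conf_d = pdist(flat)
    elif metric == "plain":
        flat = ens.coords.reshape(len(ens), -1)
        conf_d = pdist(flat) / np.sqrt(ref.n_atoms)
    else:
        raise InvalidArgumentError(f"metric must be 'mass' or 'plain', got {metric!r}")
    r = float(pearsonr(sphere_d, conf_d).statistic) if sphere_d.size > 1 else 1.0
    return CorrespondenceReport(
        min_rmsd=float(conf_d.min()),
        max_abs_diff=float(np.max(np.abs(sphere_d - conf_d))),
        pearson_r=r,
    )
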