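"""Ensemble structural metrics: hinge angle, RMSF, radius of gyration.

These are the descriptors used to characterize generated ensembles:
a breathing (hinge-opening) angle defined by the centers of mass of three
atom groups flanking a hinge, per-atom root-mean-square fluctuations after
rigid-body superposition, and the mass-weighted radius of gyration.  A
Kabsch superposition utility underlies the ensemble alignment; the
normal-mode-space operations elsewhere in the package deliberately use
no-fit distances and never superpose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import InvalidArgumentError
from .modes import Structure
from .nmspace import Ensemble

__all__ = [
    "AngleGroups",
    "LYSOZYME_BREATHING_GROUPS",
    "breathing_angle",
    "rmsf",
    "radius_of_gyration",
    "kabsch_superpose",
]


@dataclass(frozen=True)
class AngleGroups:
    """Three disjoint atom-index groups whose centers of mass define an angle."""

    a: tuple[int, ...]
    b: tuple[int, ...]
    c: tuple[int, ...]

    def __post_init__(self) -> None:
        sets = [frozenset(self.a), frozenset(self.b), frozenset(self.c)]
        if any(not s for s in sets):
            raise InvalidArgumentError("all three angle groups must be non-empty")
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise InvalidArgumentError("angle groups must be disjoint")


# Hen egg-white lysozyme hinge-bending preset (Cα residue ranges):
# (i) Trp28-Ala31 + Ala110-Asn113, (ii) Thr89-Val92, (iii) Trp43-Arg45 +
# Trp51-Tyr53.  Expressed as residue-id ranges; resolve against a real
# lysozyme structure with `angle_groups_from_residues`.
LYSOZYME_BREATHING_GROUPS = {
    "a": [(28, 31), (110, 113)],
    "b": [(89, 92)],
    "c": [(43, 45), (51, 53)],
}


def angle_groups_from_residues(st: Structure, ranges: dict, atom_name: str = "CA") -> AngleGroups:
    """Resolve residue-id ranges into atom-index groups for ``st``."""
    res_ids = np.asarray(st.res_ids)
    names = np.asarray(st.atom_names)

    def collect(pairs) -> tuple[int, ...]:
        idx: list[int] = []
        for lo, hi in pairs:
            mask = (res_ids >= lo) & (res_ids <= hi) & (names == atom_name)
            idx.extend(np.flatnonzero(mask).tolist())
        return tuple(idx)

    return AngleGroups(a=collect(ranges["a"]), b=collect(ranges["b"]), c=collect(ranges["c"]))


def _com(coords: np.ndarray, masses: np.ndarray, idx) -> np.ndarray:
    idx = np.asarray(idx, dtype=int)
    m = masses[idx]
    return (coords[idx] * m[:, None]).sum(axis=0) / m.sum()


def breathing_angle(conf: np.ndarray, st: Structure, groups: AngleGroups) -> float:
    """Angle (degrees, in [0, 180]) at the vertex COM(b) of COM(a)-COM(b)-COM(c)."""
    conf = np.asarray(conf, dtype=float)
    if conf.shape != st.coords.shape:
        raise InvalidArgumentError("conformation does not match the structure topology")
    pa = _com(conf, st.masses, groups.a)
    pb = _com(conf, st.masses, groups.b)
    pc = _com(conf, st.masses, groups.c)
    v1 = pa - pb
    v2 = pc - pb
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-10 or n2 < 1e-10:
        raise InvalidArgumentError("coincident centers of mass leave the angle undefined")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def kabsch_superpose(
    conf: np.ndarray, ref: np.ndarray, selection=None, weights=None
) -> tuple[np.ndarray, float]:
    """Optimal rigid-body alignment of ``conf`` onto ``ref``.

    The rotation is found on the (optionally selected, optionally weighted)
    atom sets; the returned coordinates are the fully transformed ``conf``
    and the RMSD is the minimized selection RMSD.
    """
    conf = np.asarray(conf, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if conf.shape != ref.shape:
        raise InvalidArgumentError("conformation and reference shapes differ")
    sel = np.arange(conf.shape[0]) if selection is None else np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise InvalidArgumentError("need at least three atoms to superpose")
    a = conf[sel]
    b = ref[sel]
    if np.linalg.matrix_rank(b - b.mean(axis=0), tol=1e-10) < 2:
        raise InvalidArgumentError("selection is collinear; rotation is underdetermined")
    w = np.ones(sel.size) if weights is None else np.asarray(weights, dtype=float)
    ca = np.average(a, axis=0, weights=w)
    cb = np.average(b, axis=0, weights=w)
    rot, _ = Rotation.align_vectors(b - cb, a - ca, weights=w)
    aligned = rot.apply(conf - ca) + cb
    diff = aligned[sel] - b
    rmsd = float(np.sqrt(np.average(np.sum(diff**2, axis=1), weights=w)))
    return aligned, rmsd


def rmsf(ens: Ensemble, selection=None, superpose: bool = True) -> pd.DataFrame:
    """Per-atom RMS fluctuation about the ensemble mean (Å).

    Each frame is first Kabsch-superposed onto the first frame (on the
    selection); fluctuations are measured against the mean of the aligned
    frames.
    """
    if len(ens) < 2:
        raise InvalidArgumentError("RMSF needs at least two conformations")
    sel = (
        np.arange(ens.structure.n_atoms)
        if selection is None
        else np.asarray(selection, dtype=int)
    )
    frames = ens.coords.copy()
    if superpose:
        for i in range(1, len(ens)):
            frames[i], _ = kabsch_superpose(frames[i], frames[0], selection=sel)
    mean = frames.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))
    return pd.DataFrame({"atom": sel, "rmsf": fluct[sel]})


def radius_of_gyration(conf: np.ndarray, masses) -> float:
    """Mass-weighted RMS distance from the center of mass (Å)."""
    conf = np.atleast_2d(np.asarray(conf, dtype=float))
    masses = np.asarray(masses, dtype=float)
    com = (conf * masses[:, None]).sum(axis=0) / masses.sum()
    d2 = np.sum((conf - com) ** 2, axis=1)
    return float(np.sqrt(np.sum(masses * d2) / masses.sum()))
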