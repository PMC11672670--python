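"""File formats, toy fixtures, and run configuration.

PDB reading and writing is backed by biotite (fixed-width v3.3 layout,
multi-model files).  Single-model files load as a :class:`Structure`,
multi-model files as an :class:`Ensemble`.  Masses are assigned from an
internal element table.

The toy structures are connected bead models with the canonical Cα-Cα
spacing of 3.8 Å: a helical chain, a planar ring, and a "helix-hinge" —
two helical arms meeting at a vertex, whose softest elastic-network modes
include a hinge-bending motion.  They stand in for protein geometry at
desk scale so nothing ever needs downloading.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile
from pydantic import BaseModel, ConfigDict, Field
from scipy.spatial.transform import Rotation

from .errors import FormatError, InvalidArgumentError
from .modes import ATOMIC_MASSES, Structure
from .nmspace import Ensemble

__all__ = [
    "read_pdb",
    "write_pdb",
    "make_toy_structure",
    "RunConfig",
]

_BEAD_SPACING = 3.8  # Å, canonical Cα-Cα distance


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


def _validate_pdb_text(path) -> None:
    """Light pre-scan: malformed ATOM lines and inconsistent model sizes."""
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise FormatError(f"line {lineno}: ATOM record shorter than 54 columns")
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise FormatError(
                        f"line {lineno}: unparseable coordinate field in ATOM record"
                    ) from None
                current += 1
            elif rec == "MODEL":
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                current = 0
    if not in_model:
        counts = [current]
    if len(set(c for c in counts if c > 0)) > 1:
        raise FormatError(f"inconsistent atom counts across models: {counts}")


def _masses_for(elements, atom_names) -> np.ndarray:
    masses = np.empty(len(elements))
    for i, (el, name) in enumerate(zip(elements, atom_names)):
        key = str(el).strip().upper() or str(name).strip()[:1].upper()
        masses[i] = ATOMIC_MASSES.get(key, 12.011)
    return masses


def _to_structure(arr: AtomArray) -> Structure:
    return Structure(
        coords=np.asarray(arr.coord, dtype=float),
        masses=_masses_for(arr.element, arr.atom_name),
        atom_names=[str(s) for s in arr.atom_name],
        res_names=[str(s) for s in arr.res_name],
        res_ids=np.asarray(arr.res_id, dtype=int),
        chain_ids=[str(s) for s in arr.chain_id],
    )


def read_pdb(path) -> Structure | Ensemble:
    """Read a PDB file: one model -> Structure, several -> Ensemble."""
    _validate_pdb_text(path)
    pdbf = PDBFile.read(str(path))
    stack = pdbf.get_structure(model=None)
    st = _to_structure(stack[0])
    if stack.stack_depth() == 1:
        return st
    return Ensemble(
        structure=st,
        coords=np.asarray(stack.coord, dtype=float),
        tags=[{"model": m + 1} for m in range(stack.stack_depth())],
    )


def _element_guess(name: str) -> str:
    stripped = name.strip()
    if stripped[:2].upper() in ATOMIC_MASSES and not stripped[:1].isdigit():
        two = stripped[:2].upper()
        if two in ("FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "SE"):
            return two
    return stripped[:1].upper()


def _as_atom_array(st: Structure, coords: np.ndarray) -> AtomArray:
    n = st.n_atoms
    arr = AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = np.array(st.atom_names)
    arr.res_name = np.array(st.res_names)
    arr.res_id = np.asarray(st.res_ids, dtype=int)
    arr.chain_id = np.array(st.chain_ids)
    arr.element = np.array([_element_guess(a) for a in st.atom_names])
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_pdb(obj: Structure | Ensemble, path) -> None:
    """Write a Structure (single model) or Ensemble (MODEL blocks) as PDB v3.3."""
    if isinstance(obj, Structure):
        atoms = _as_atom_array(obj, obj.coords)
    elif isinstance(obj, Ensemble):
        frames = [_as_atom_array(obj.structure, c) for c in obj.coords]
        atoms = AtomArrayStack(len(frames), obj.structure.n_atoms)
        for key in ("atom_name", "res_name", "res_id", "chain_id", "element", "hetero"):
            atoms.set_annotation(key, frames[0].get_annotation(key))
        atoms.coord = np.stack([f.coord for f in frames])
    else:
        raise InvalidArgumentError(f"cannot write object of type {type(obj).__name__}")
    pdbf = PDBFile()
    pdbf.set_structure(atoms)
    pdbf.write(str(path))


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------


def _helix_points(n: int) -> np.ndarray:
    """Helical bead curve with consecutive spacing exactly 3.8 Å."""
    radius = 2.3
    turn = np.radians(100.0)
    chord = 2.0 * radius * np.sin(turn / 2.0)
    rise = float(np.sqrt(_BEAD_SPACING**2 - chord**2))
    t = np.arange(n)
    return np.column_stack(
        [radius * np.cos(turn * t), radius * np.sin(turn * t), rise * t]
    )


def make_toy_structure(
    n_atoms: int,
    kind: str = "chain",
    seed: int = 0,
    mass_pattern: str = "uniform",
) -> Structure:
    """Connected bead model with nearest-neighbor spacing 3.8 Å.

    Kinds: ``chain`` (helical curve), ``ring`` (planar circle; degenerate
    for elastic-network modes, intended for geometric tests), and
    ``helix-hinge`` (two helical arms meeting at a vertex, so the softest
    elastic-network modes include hinge bending).  The seed applies a random
    global rotation, which changes nothing physical but decorrelates
    coordinate axes between fixtures.  ``mass_pattern`` is ``uniform``
    (1 amu beads) or ``backbone`` (cycling C, N, C, O element masses, a
    heterogeneous-mass fixture).
    """
    if n_atoms < 6:
        raise InvalidArgumentError("toy structures need at least 6 atoms")
    if kind == "chain":
        coords = _helix_points(n_atoms)
    elif kind == "ring":
        r = _BEAD_SPACING / (2.0 * np.sin(np.pi / n_atoms))
        ang = 2.0 * np.pi * np.arange(n_atoms) / n_atoms
        coords = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n_atoms)])
    elif kind == "helix-hinge":
        if n_atoms < 9:
            raise InvalidArgumentError("helix-hinge needs at least 9 atoms")
        coords = _helix_points(n_atoms)
        pivot = n_atoms // 2
        # bend the second arm ~70 degrees about the pivot bead
        rot = Rotation.from_rotvec(np.radians(70.0) * np.array([1.0, 0.0, 0.0]))
        coords[pivot + 1 :] = rot.apply(coords[pivot + 1 :] - coords[pivot]) + coords[pivot]
    else:
        raise InvalidArgumentError(f"unknown toy kind {kind!r}")
    rng = np.random.default_rng(seed)
    coords = coords @ Rotation.random(random_state=rng).as_matrix().T
    coords -= coords.mean(axis=0)
    if mass_pattern == "uniform":
        masses = np.ones(n_atoms)
    elif mass_pattern == "backbone":
        cycle = np.array(
            [ATOMIC_MASSES["C"], ATOMIC_MASSES["N"], ATOMIC_MASSES["C"], ATOMIC_MASSES["O"]]
        )
        masses = cycle[np.arange(n_atoms) % 4]
    else:
        raise InvalidArgumentError(f"unknown mass pattern {mass_pattern!r}")
    return Structure(
        coords=coords,
        masses=masses,
        atom_names=["CA"] * n_atoms,
        res_names=["GLY"] * n_atoms,
        res_ids=np.arange(1, n_atoms + 1),
        chain_ids=["A"] * n_atoms,
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


class RunConfig(BaseModel):
    """Schema-validated parameters for a full pipeline run.

    Unknown keys are rejected; the resolved document is written next to the
    outputs of every run so each artifact directory is self-describing.
    """

    model_config = ConfigDict(extra="forbid")

    # hypersphere
    dim: int = Field(default=2, ge=2)
    n_points: int | None = Field(default=None, description="None = kissing preset")
    mirrored: bool = True
    seed: int = 0
    restarts: int = Field(default=1, ge=1)
    alpha: float | None = None
    grad_tol: float = Field(default=0.001, gt=0)
    max_cycles: int = Field(default=10, ge=1)
    # structure source
    pdb: str | None = Field(default=None, description="None = toy structure")
    toy_atoms: int = Field(default=50, ge=6)
    toy_kind: str = "helix-hinge"
    toy_mass_pattern: str = "uniform"
    # elastic network
    cutoff: float = Field(default=12.0, gt=0)
    gamma: float = Field(default=1.0, gt=0)
    # displacement / dpVAC
    amplitude: float = Field(default=1.0, ge=0)
    metric: str = "mass"
    k_mod: float = Field(default=1.0e4, gt=0)
    step: float = Field(default=0.1, gt=0)
    d_max: float = Field(default=3.0, gt=0)
    model: str = Field(default="enm", description="'enm' or 'null'")
    axes: tuple[int, int] = (7, 8)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
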