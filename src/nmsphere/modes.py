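"""Structures and mass-weighted normal modes from an elastic network model.

The elastic network (anisotropic network) model places identical harmonic
springs between every atom pair closer than a cutoff.  Its mass-weighted
Hessian is diagonalized, the six near-zero rigid-body eigenpairs are
discarded, and the remaining low-frequency eigenvectors serve as the
normal-mode basis.  Modes are stored in mass-weighted coordinates
(components scaled by sqrt(m_i)) with plain unit norm, so that displacing a
structure by amplitude ``a`` along a mode produces a mass-weighted RMSD of
exactly ``a``.  Mode labels start at 7, after the six rigid-body modes.

Eigenvalues are in units of the spring constant gamma (not cm^-1); only the
mode shapes and their ordering matter downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components

from .errors import (
    DegenerateStructureError,
    FormatError,
    InvalidArgumentError,
)

logger = logging.getLogger("nmsphere")

__all__ = [
    "Structure",
    "ModeSet",
    "build_enm_hessian",
    "compute_modes",
    "enm_modes",
    "save_modes",
    "load_modes",
    "ATOMIC_MASSES",
]

# standard atomic masses (amu) for elements commonly found in PDB files
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "MN": 54.938, "CU": 63.546, "NA": 22.990, "K": 39.098,
    "CL": 35.45, "F": 18.998, "BR": 79.904, "I": 126.904,
}

_RIGID_BODY_COUNT = 6


@dataclass
class Structure:
    """A single conformation: coordinates in Å plus per-atom metadata."""

    coords: np.ndarray
    masses: np.ndarray
    atom_names: list[str] = field(default_factory=list)
    res_names: list[str] = field(default_factory=list)
    res_ids: np.ndarray | None = None
    chain_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidArgumentError("coords must have shape (N, 3)")
        if n < 2:
            raise InvalidArgumentError("a Structure needs at least two atoms")
        if self.masses.shape != (n,):
            raise InvalidArgumentError("masses must be one positive value per atom")
        if not np.all(self.masses > 0):
            raise InvalidArgumentError("all masses must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidArgumentError("coordinates must be finite")
        if not self.atom_names:
            self.atom_names = ["CA"] * n
        if not self.res_names:
            self.res_names = ["GLY"] * n
        if self.res_ids is None:
            self.res_ids = np.arange(1, n + 1)
        if not self.chain_ids:
            self.chain_ids = ["A"] * n

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def mass_weights(self) -> np.ndarray:
        """Per-coordinate sqrt(m_i / M) factors, shape (3 N,)."""
        return np.repeat(np.sqrt(self.masses / self.total_mass), 3)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(
            coords=np.asarray(coords, dtype=float),
            masses=self.masses,
            atom_names=list(self.atom_names),
            res_names=list(self.res_names),
            res_ids=self.res_ids.copy(),
            chain_ids=list(self.chain_ids),
        )


@dataclass
class ModeSet:
    """Orthonormal mass-weighted normal-mode vectors with eigenvalues.

    ``vectors`` has one mode per row, length 3*N_atoms, expressed in
    mass-weighted coordinates with plain unit norm; the rows therefore form
    an orthonormal basis in the mass-weighted inner product on Cartesian
    displacements.  ``labels`` follow the convention that internal modes
    start at 7.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    masses: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        k, width = self.vectors.shape
        if width != 3 * self.masses.shape[0]:
            raise InvalidArgumentError(
                f"mode vectors of length {width} do not match {self.masses.shape[0]} atoms"
            )
        if self.eigenvalues.shape != (k,):
            raise InvalidArgumentError("one eigenvalue per mode required")
        if self.labels is None:
            self.labels = np.arange(7, 7 + k)
        else:
            self.labels = np.asarray(self.labels, dtype=int)
        gram = self.vectors @ self.vectors.T
        if np.max(np.abs(np.diag(gram) - 1.0)) > 1e-8:
            raise InvalidArgumentError("mode vectors must have unit mass-weighted norm")
        if np.max(np.abs(gram - np.eye(k))) > 1e-8:
            warnings.warn(
                "mode vectors are not mutually orthogonal in the mass-weighted metric",
                stacklevel=2,
            )

    @property
    def k(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.masses.shape[0]

    def vector_for(self, label: int) -> np.ndarray:
        idx = np.flatnonzero(self.labels == label)
        if idx.size != 1:
            raise InvalidArgumentError(f"no mode labeled {label} in this ModeSet")
        return self.vectors[idx[0]]


def build_enm_hessian(st: Structure, cutoff: float = 12.0, gamma: float = 1.0) -> np.ndarray:
    """Anisotropic-network Hessian: springs between all pairs within cutoff.

    The 3x3 off-diagonal block for a contacting pair (i, j) is
    ``-gamma * (d d^T) / |d|^2`` with ``d = r_j - r_i``; diagonal blocks are
    minus the sum of the row's off-diagonal blocks, making rigid translations
    exact zero modes.
    """
    if cutoff <= 0 or gamma <= 0:
        raise InvalidArgumentError("cutoff and gamma must be positive")
    x = st.coords
    n = st.n_atoms
    diff = x[:, None, :] - x[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    contact = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    n_comp, _ = connected_components(contact, directed=False)
    if n_comp == n:
        raise DegenerateStructureError("no atom pair within the cutoff; network is empty")
    isolated = np.flatnonzero(~contact.any(axis=1))
    if isolated.size:
        warnings.warn(
            f"atoms {isolated.tolist()} have no contacts within cutoff {cutoff} Å",
            stacklevel=2,
        )
    if n_comp > 1:
        warnings.warn(
            f"elastic network has {n_comp} connected components; "
            "extra zero modes will appear",
            stacklevel=2,
        )
    hess = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(contact, 1))
    for i, j in zip(ii, jj):
        d = diff[j, i]  # r_j - r_i
        block = -gamma * np.outer(d, d) / (dist[i, j] ** 2)
        hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hess[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hess[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hess


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component of each mode positive."""
    out = vectors.copy()
    for row in out:
        k = int(np.argmax(np.abs(row)))
        if row[k] < 0:
            row *= -1.0
    return out


def compute_modes(hessian: np.ndarray, masses, k: int) -> ModeSet:
    """Diagonalize the mass-weighted Hessian and keep ``k`` internal modes.

    The detected near-zero rigid-body eigenpairs are discarded (six for a
    three-dimensional structure, five for a linear one; more raises a
    degeneracy error); the next ``k`` eigenvectors, in ascending eigenvalue
    order, are returned labeled 7..(6+k).
    """
    masses = np.asarray(masses, dtype=float)
    hessian = np.asarray(hessian, dtype=float)
    n3 = hessian.shape[0]
    if hessian.shape != (n3, n3) or np.max(np.abs(hessian - hessian.T)) > 1e-10:
        raise InvalidArgumentError("hessian must be a symmetric square matrix")
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if n3 != 3 * masses.shape[0]:
        raise InvalidArgumentError("hessian size does not match the number of atoms")
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), 3)
    mw = hessian * np.outer(inv_sqrt_m, inv_sqrt_m)
    mw = 0.5 * (mw + mw.T)
    evals, evecs = eigh(mw)
    scale = max(np.max(np.abs(evals)), 1.0)
    near_zero = np.abs(evals) <= 1e-8 * scale
    n_rigid = int(near_zero.sum())
    if n_rigid > _RIGID_BODY_COUNT:
        raise DegenerateStructureError(
            f"{n_rigid} near-zero eigenvalues found "
            f"(at most {_RIGID_BODY_COUNT} rigid-body modes expected); "
            "the structure or network is degenerate"
        )
    # drop the detected rigid-body modes (6 for a 3-D structure, 5 for a
    # linear one); keep the rest ascending by eigenvalue
    internal = np.flatnonzero(~near_zero)
    internal = internal[np.argsort(evals[internal])]
    if k > internal.size:
        raise InvalidArgumentError(
            f"requested {k} modes but only {internal.size} internal modes exist"
        )
    sel = internal[:k]
    vectors = _fix_signs(evecs[:, sel].T)
    return ModeSet(vectors=vectors, eigenvalues=evals[sel], masses=masses)


def enm_modes(st: Structure, k: int = 8, cutoff: float = 12.0, gamma: float = 1.0) -> ModeSet:
    """Convenience: ENM Hessian from ``st`` followed by :func:`compute_modes`."""
    return compute_modes(build_enm_hessian(st, cutoff=cutoff, gamma=gamma), st.masses, k)


# ---------------------------------------------------------------------------
# mode matrix file format
# ---------------------------------------------------------------------------


def save_modes(ms: ModeSet, path) -> None:
    """Write a mode matrix: comment header, then one whitespace row per mode."""
    with open(path, "w") as fh:
        fh.write(f"# nmsphere modes natoms={ms.n_atoms} k={ms.k} mass_weighted=true\n")
        fh.write("# eigenvalues " + " ".join(f"{v:.17g}" for v in ms.eigenvalues) + "\n")
        fh.write("# labels " + " ".join(str(v) for v in ms.labels) + "\n")
        fh.write("# masses " + " ".join(f"{v:.17g}" for v in ms.masses) + "\n")
        for row in ms.vectors:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def load_modes(path, st: Structure) -> ModeSet:
    """Read a mode matrix (native or NMD ``mode``-line dialect) for ``st``.

    Rows are re-normalized to unit mass-weighted norm; a notice is logged,
    with the Gram matrix, if any correction exceeds 1e-6.
    """
    rows: list[np.ndarray] = []
    eigenvalues: np.ndarray | None = None
    labels: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#") or line.startswith("@"):
                tokens = line.lstrip("#@").split()
                if tokens and tokens[0] == "eigenvalues":
                    eigenvalues = np.array([float(t) for t in tokens[1:]])
                continue
            tokens = line.split()
            if tokens[0].lower() == "mode":
                # NMD dialect: mode <label> [<scale>] x1 y1 z1 ...
                values = [float(t) for t in tokens[1:]]
                extra = len(values) - 3 * st.n_atoms
                if extra < 0:
                    raise FormatError(
                        f"line {lineno}: mode row has {len(values)} components, "
                        f"expected at least {3 * st.n_atoms}"
                    )
                if extra >= 1:
                    labels.append(int(values[0]))
                rows.append(np.array(values[extra:]))
            else:
                values = np.array([float(t) for t in tokens])
                if values.size != 3 * st.n_atoms:
                    raise FormatError(
                        f"line {lineno}: mode row has {values.size} components, "
                        f"expected {3 * st.n_atoms} for {st.n_atoms} atoms"
                    )
                rows.append(values)
    if not rows:
        raise FormatError(f"no mode rows found in {path}")
    vectors = np.vstack(rows)
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise FormatError("zero-length mode vector")
    if np.max(np.abs(norms - 1.0)) > 1e-6:
        gram = np.round((vectors / norms[:, None]) @ (vectors / norms[:, None]).T, 6)
        logger.warning(
            "mode vectors re-normalized (max norm deviation %.3g); Gram matrix:\n%s",
            float(np.max(np.abs(norms - 1.0))),
            gram,
        )
    vectors = vectors / norms[:, None]
    if eigenvalues is None or eigenvalues.size != vectors.shape[0]:
        eigenvalues = np.zeros(vectors.shape[0])
    lab = np.array(labels, dtype=int) if len(labels) == vectors.shape[0] else None
    return ModeSet(vectors=vectors, eigenvalues=eigenvalues, masses=st.masses, labels=lab)
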