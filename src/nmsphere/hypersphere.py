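"""Uniform point distributions on the unit hypersphere.

Points on a D-dimensional unit hypersphere are dispersed by minimizing an
inverse-power (Riesz) pair energy

    E = alpha * sum_{i<j} r_ij**(-s)

subject to every point staying on the sphere.  As the exponent ``s`` grows
the minimizers of E approach best-packing (maximin-distance) configurations,
so the minimization is run as a continuation: a schedule of increasing
exponents, each cycle warm-started from the previous one.  The uniformity
diagnostic throughout is ``Mdist``, the minimal pairwise Euclidean distance.

Two algorithms are provided:

* plain projected-gradient descent from a random start (``minimize``);
* a mirrored variant (``minimize_mirrored``) that optimizes antipodal point
  pairs jointly.  Kissing-number configurations are centrally symmetric, so
  constraining the search to antipodal pairs removes most spurious local
  minima and reaches the optimal packing reliably.

Energies are evaluated in the log domain: at large ``s`` the raw sum
overflows double precision long before the configuration degenerates, while
``log E`` stays perfectly well behaved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import logsumexp

from .errors import DivergenceError, InvalidArgumentError, UnsupportedDimensionError

__all__ = [
    "PointSet",
    "StepRule",
    "MinimizationConfig",
    "MinimizationTrace",
    "init_points",
    "riesz_energy",
    "mdist",
    "neighbor_counts",
    "kissing_preset",
    "minimize",
    "minimize_mirrored",
    "minimize_preset",
]

# Kissing numbers for dimensions 2..8: the maximal number of unit spheres
# that can touch a central unit sphere.  Used as preset point counts.
_KISSING = {2: 6, 3: 12, 4: 24, 5: 40, 6: 72, 7: 126, 8: 240}

_UNIT_NORM_TOL = 1e-12


# ---------------------------------------------------------------------------
# point sets
# ---------------------------------------------------------------------------


@dataclass
class PointSet:
    """N points on the D-dimensional unit hypersphere.

    Parameters
    ----------
    dim
        Hypersphere dimension D (>= 2).
    points
        Array of shape (N, D); every row must have unit Euclidean norm.
    """

    dim: int
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.dim < 2:
            raise InvalidArgumentError(f"hypersphere dimension must be >= 2, got {self.dim}")
        if self.points.ndim != 2 or self.points.shape[1] != self.dim:
            raise InvalidArgumentError(
                f"points must be an (N, {self.dim}) array, got shape {self.points.shape}"
            )
        if self.points.shape[0] < 1:
            raise InvalidArgumentError("a PointSet needs at least one point")
        norms = np.linalg.norm(self.points, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-9:
            raise InvalidArgumentError("all points must lie on the unit hypersphere")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def is_mirrored(self, tol: float = 1e-9) -> bool:
        """True if the set is closed under negation, point for point."""
        if self.n % 2:
            return False
        remaining = list(range(self.n))
        pts = self.points
        while remaining:
            i = remaining.pop(0)
            d = np.linalg.norm(pts[remaining] + pts[i], axis=1) if remaining else np.array([])
            if d.size == 0 or d.min() > tol:
                return False
            remaining.pop(int(np.argmin(d)))
        return True

    def to_csv(self, path) -> None:
        cols = [f"x{k + 1}" for k in range(self.dim)]
        df = pd.DataFrame(self.points, columns=cols)
        df.insert(0, "index", np.arange(self.n))
        df.insert(0, "dim", self.dim)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PointSet":
        df = pd.read_csv(path)
        dim = int(df["dim"].iloc[0])
        pts = df[[f"x{k + 1}" for k in range(dim)]].to_numpy(dtype=float)
        # round-tripping through text may nudge norms off by ~1e-16
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        return cls(dim=dim, points=pts)


def init_points(n: int, dim: int, seed: int) -> PointSet:
    """Random points uniform on the unit hypersphere (normalized Gaussians)."""
    if n < 1:
        raise InvalidArgumentError(f"need n >= 1 points, got {n}")
    if dim < 2:
        raise InvalidArgumentError(f"need dim >= 2, got {dim}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, dim))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    return PointSet(dim=dim, points=x)


def kissing_preset(dim: int) -> int:
    """Preset point count for dimension ``dim``: the kissing number (D=2..8)."""
    try:
        return _KISSING[dim]
    except KeyError:
        raise UnsupportedDimensionError(
            f"kissing presets cover dimensions 2..8, got {dim}"
        ) from None


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def mdist(ps: PointSet | np.ndarray) -> float:
    """Minimal pairwise Euclidean distance of a point set."""
    pts = ps.points if isinstance(ps, PointSet) else np.asarray(ps, dtype=float)
    if pts.shape[0] < 2:
        raise InvalidArgumentError("Mdist needs at least two points")
    return float(pdist(pts).min())


def neighbor_counts(ps: PointSet, rel_tol: float = 0.005) -> np.ndarray:
    """Per-point count of others at distance within ``rel_tol * Mdist`` of Mdist."""
    if ps.n < 2:
        raise InvalidArgumentError("neighbor counts need at least two points")
    if not 0.0 < rel_tol <= 0.1:
        raise InvalidArgumentError(f"rel_tol must be in (0, 0.1], got {rel_tol}")
    dm = squareform(pdist(ps.points))
    np.fill_diagonal(dm, np.inf)
    m = dm.min()
    return (dm <= m * (1.0 + rel_tol)).sum(axis=1)


def riesz_energy(ps: PointSet | np.ndarray, alpha: float, s: float) -> float:
    """Inverse-power pair energy ``alpha * sum_{i<j} r_ij**(-s)``."""
    pts = ps.points if isinstance(ps, PointSet) else np.asarray(ps, dtype=float)
    if pts.shape[0] < 2:
        return 0.0
    d = pdist(pts)
    if d.min() == 0.0:
        idx = np.argmin(d)
        i, j = _condensed_to_pair(idx, pts.shape[0])
        raise DivergenceError(f"points {i} and {j} coincide; pair energy diverges")
    return float(alpha * np.exp(logsumexp(-s * np.log(d))))


def _condensed_to_pair(k: int, n: int) -> tuple[int, int]:
    # invert the condensed pdist index
    i = int(n - 2 - np.floor(np.sqrt(-8 * k + 4 * n * (n - 1) - 7) / 2.0 - 0.5))
    j = int(k + i + 1 - n * (n - 1) // 2 + (n - i) * ((n - i) - 1) // 2)
    return i, j


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepRule:
    """Adaptive step-size policy for the projected-gradient descent.

    The step length bounds the largest single-point displacement per
    iteration; it grows after an immediately accepted step and shrinks while
    backtracking.
    """

    initial: float = 0.1
    grow: float = 1.5
    shrink: float = 0.5
    max_step: float = 0.5
    min_step: float = 1e-13


@dataclass(frozen=True)
class MinimizationConfig:
    """Settings for hypersphere energy minimization.

    ``s_schedule`` is the exponent continuation; by default it doubles from 1
    for ``max_cycles`` cycles (1, 2, 4, ..., 512), driving the minimizer
    toward the best-packing limit.  ``alpha`` defaults to ``1/N**2`` so the
    energy stays O(1) regardless of the point count.  ``grad_tol`` bounds the
    largest per-point projected-gradient norm of ``log E`` at cycle
    termination; log-domain gradients stay O(1)-scaled even at the largest
    exponents, so one tolerance serves every cycle.
    """

    alpha: float | None = None
    s_schedule: tuple[float, ...] | None = None
    grad_tol: float = 0.001
    max_cycles: int = 10
    max_iter_per_cycle: int = 400
    step_rule: StepRule = field(default_factory=StepRule)
    seed: int = 0
    mirrored: bool = False

    def __post_init__(self) -> None:
        if self.grad_tol <= 0:
            raise InvalidArgumentError("grad_tol must be positive")
        if self.max_cycles < 1:
            raise InvalidArgumentError("max_cycles must be >= 1")
        if self.s_schedule is not None:
            sched = tuple(float(s) for s in self.s_schedule)
            if not sched or any(s <= 0 for s in sched):
                raise InvalidArgumentError("s_schedule must be non-empty and positive")
            if any(b <= a for a, b in zip(sched, sched[1:])):
                raise InvalidArgumentError("s_schedule must be strictly increasing")
            object.__setattr__(self, "s_schedule", sched)
        if self.alpha is not None and self.alpha <= 0:
            raise InvalidArgumentError("alpha must be positive")

    def resolved_schedule(self) -> tuple[float, ...]:
        if self.s_schedule is not None:
            return self.s_schedule
        return tuple(float(2**c) for c in range(self.max_cycles))

    def resolved_alpha(self, n: int) -> float:
        return self.alpha if self.alpha is not None else 1.0 / n**2


@dataclass
class MinimizationTrace:
    """Per-iteration record of a minimization run.

    ``energy`` is the raw Riesz energy (``inf`` where it overflows a double);
    ``log_energy`` is always finite and is what the descent monotonicity
    guarantees refer to.
    """

    records: list[dict] = field(default_factory=list)
    seed: int = 0
    converged: bool = True

    def append(self, cycle: int, iteration: int, s: float, log_energy: float, md: float) -> None:
        with np.errstate(over="ignore"):
            energy = float(np.exp(log_energy))
        self.records.append(
            {
                "cycle": cycle,
                "iter": iteration,
                "s": s,
                "energy": energy,
                "log_energy": float(log_energy),
                "mdist": float(md),
            }
        )

    @property
    def final_mdist(self) -> float:
        return self.records[-1]["mdist"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["cycle", "iter", "s", "energy", "mdist"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _log_energy_and_gradlog(
    x: np.ndarray, s: float, log_alpha: float
) -> tuple[float, np.ndarray]:
    """Return (log E, gradient of log E) for the full point set ``x``.

    Both are computed with a shared log-domain shift so the ratio defining
    grad(log E) never overflows, even at s in the hundreds.
    """
    n = x.shape[0]
    diff = x[:, None, :] - x[None, :, :]
    dm = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(n, 1)
    d = dm[iu]
    if d.min() == 0.0:
        k = int(np.argmin(d))
        raise DivergenceError(
            f"points {iu[0][k]} and {iu[1][k]} coincide; pair energy diverges"
        )
    logd = np.log(d)
    shift = float(np.max(-s * logd))
    log_e = log_alpha + shift + np.log(np.sum(np.exp(-s * logd - shift)))
    # grad log E = [-s * sum_j d_ij^(-s-2) (x_i - x_j)] / sum_pairs d^(-s)
    np.fill_diagonal(dm, 1.0)
    w = np.exp(-(s + 2.0) * np.log(dm) - shift)
    np.fill_diagonal(w, 0.0)
    denom = float(np.sum(np.exp(-s * logd - shift)))
    grad = -s * np.einsum("ij,ijk->ik", w, diff) / denom
    return float(log_e), grad


def _tangent_project(grad: np.ndarray, x: np.ndarray) -> np.ndarray:
    return grad - np.sum(grad * x, axis=1, keepdims=True) * x


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def _descend(
    x_free: np.ndarray,
    cfg: MinimizationConfig,
    mirrored: bool,
    trace: MinimizationTrace,
) -> np.ndarray:
    """Projected-gradient continuation descent; returns the free-point block.

    For mirrored runs ``x_free`` holds one point of each antipodal pair; the
    energy and Mdist are always those of the full (doubled) set.
    """

    def full(xf: np.ndarray) -> np.ndarray:
        return np.vstack([xf, -xf]) if mirrored else xf

    n_total = (2 if mirrored else 1) * x_free.shape[0]
    log_alpha = np.log(cfg.resolved_alpha(n_total))
    rule = cfg.step_rule
    step = rule.initial
    schedule = cfg.resolved_schedule()
    converged_final = n_total < 2

    x = x_free.copy()
    for cycle, s in enumerate(schedule):
        if n_total < 2:
            trace.append(cycle, 0, s, -np.inf, np.nan)
            continue
        cycle_converged = False
        for it in range(cfg.max_iter_per_cycle):
            log_e, grad = _log_energy_and_gradlog(full(x), s, log_alpha)
            if mirrored:
                nh = x.shape[0]
                grad = grad[:nh] - grad[nh:]
            p = _tangent_project(grad, x)
            md = mdist(full(x))
            trace.append(cycle, it, s, log_e, md)
            pmax = float(np.max(np.linalg.norm(p, axis=1)))
            if pmax <= cfg.grad_tol:
                cycle_converged = True
                break
            direction = -p / pmax
            accepted = False
            first_try = True
            while step >= rule.min_step:
                x_new = _normalize_rows(x + step * direction)
                log_e_new, _ = _log_energy_and_gradlog(full(x_new), s, log_alpha)
                if log_e_new < log_e:
                    x = x_new
                    if first_try:
                        step = min(step * rule.grow, rule.max_step)
                    accepted = True
                    break
                step *= rule.shrink
                first_try = False
            if not accepted:
                # no descent direction at floating-point resolution
                cycle_converged = True
                step = rule.initial * rule.shrink**4
                break
        converged_final = cycle_converged
        step = max(step, rule.initial * rule.shrink**6)
    trace.converged = bool(converged_final)
    return x


def minimize(
    ps: PointSet, cfg: MinimizationConfig, restarts: int = 1
) -> tuple[PointSet, MinimizationTrace]:
    """Disperse ``ps`` by plain projected-gradient Riesz-energy descent.

    With ``restarts > 1`` the first run starts from ``ps`` and subsequent
    runs from fresh random sets seeded ``cfg.seed + r``; the run with the
    largest final Mdist wins.
    """
    if restarts < 1:
        raise InvalidArgumentError("restarts must be >= 1")
    best: tuple[PointSet, MinimizationTrace] | None = None
    for r in range(restarts):
        start = ps if r == 0 else init_points(ps.n, ps.dim, cfg.seed + r)
        trace = MinimizationTrace(seed=cfg.seed if r == 0 else cfg.seed + r)
        x = _descend(start.points.copy(), cfg, mirrored=False, trace=trace)
        result = PointSet(dim=ps.dim, points=x)
        if best is None or trace.final_mdist > best[1].final_mdist:
            best = (result, trace)
    return best


def minimize_mirrored(
    n_half: int, dim: int, cfg: MinimizationConfig, restarts: int = 1
) -> tuple[PointSet, MinimizationTrace]:
    """Mirrored minimization of ``2 * n_half`` points closed under negation.

    Only ``n_half`` points are free variables; each carries its exact
    antipode, and the energy includes every pair interaction of the full set.
    Returns the restart with the largest final Mdist.
    """
    if n_half < 1:
        raise InvalidArgumentError("n_half must be >= 1")
    if dim < 2:
        raise InvalidArgumentError(f"need dim >= 2, got {dim}")
    if restarts < 1:
        raise InvalidArgumentError("restarts must be >= 1")
    best: tuple[PointSet, MinimizationTrace] | None = None
    for r in range(restarts):
        seed = cfg.seed + r
        start = init_points(n_half, dim, seed)
        trace = MinimizationTrace(seed=seed)
        x = _descend(start.points.copy(), cfg, mirrored=True, trace=trace)
        result = PointSet(dim=dim, points=np.vstack([x, -x]))
        if best is None or trace.final_mdist > best[1].final_mdist:
            best = (result, trace)
    return best


def minimize_preset(
    dim: int,
    cfg: MinimizationConfig | None = None,
    restarts: int = 1,
    target_mdist: float | None = None,
    max_restarts: int | None = None,
) -> tuple[PointSet, MinimizationTrace]:
    """Converge the kissing-number preset for ``dim`` by mirrored descent.

    If ``target_mdist`` is given, restarts continue (up to ``max_restarts``)
    until the best run reaches it.
    """
    cfg = cfg or MinimizationConfig()
    n_half = kissing_preset(dim) // 2
    best = minimize_mirrored(n_half, dim, cfg, restarts=restarts)
    if target_mdist is not None:
        r = restarts
        cap = max_restarts if max_restarts is not None else restarts
        while best[1].final_mdist < target_mdist and r < cap:
            cand = minimize_mirrored(n_half, dim, replace(cfg, seed=cfg.seed + r), restarts=1)
            if cand[1].final_mdist > best[1].final_mdist:
                best = cand
            r += 1
    return best
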