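# Methods

## Point distributions on the hypersphere

Points constrained to the D-dimensional unit hypersphere are dispersed by
minimizing the inverse-power pair energy E = α Σ_{i<j} r_ij^{−s} over
unordered pairs (an all-ordered-pairs convention would only double E and
cannot move the minima).  As s → ∞ the minimizers approach best-packing
(maximin) configurations, so the optimization is a continuation: the
exponent schedule defaults to s = 1, 2, 4, …, doubling once per cycle for
`max_cycles` = 10 cycles (final s = 512).  α defaults to 1/N², keeping E of
order one; since all energies are evaluated in the log domain (see below),
α affects reported values only, never the optimization path.

Each cycle runs projected gradient descent: the Euclidean gradient of
log E is projected onto every point's tangent space, the step moves each
point at most `step` along the normalized direction, and the point is
renormalized to the sphere.  The step length adapts (grow ×1.5 on an
immediately accepted step, shrink ×0.5 while backtracking); only
energy-decreasing steps are accepted, which guarantees monotone energy
within a cycle.  A cycle terminates when the largest per-point projected
gradient of log E falls below `grad_tol` (default 0.001) or after
`max_iter_per_cycle` = 400 iterations.  The criterion is deliberately *not*
rescaled by s: at the final exponent the undivided criterion corresponds to
point-position accuracy of roughly 1e-8 on the small benchmark
configurations, which is what lets the D = 2 minimizer hit the analytic
circle optimum 2·sin(π/N) to better than 1e-6.

**Numerical stability.** At s = 512 a raw pair term r^−s overflows double
precision whenever r < ~0.27, long before a random configuration is
degenerate.  All energies are therefore computed as log E via a shifted
log-sum-exp, and the gradient of log E is formed with the same shift so the
ratio never overflows.  The trace records both log E (always finite, used
for all monotonicity guarantees) and E itself (inf where it overflows).

**Mirrored variant.** Kissing-number configurations are centrally
symmetric, so the mirrored algorithm stores one free point per antipodal
pair and builds the full 2n-point set as [X; −X].  The gradient of the full
energy with respect to a free point is the difference of the gradients at
the point and at its antipode; steps and renormalization act on the free
half only, so closure under negation is exact by construction.  This
constraint removes most of the spurous local minima that trap plain
random-start descent: measured under the defaults, plain descent finds the
optimal D = 4 packing in ~5 of 100 random starts, the mirrored variant in
20 of 20.

Both entry points accept a restart count and return the run with the
largest final Mdist; the 240-point 8-dimensional preset typically converges
to Mdist = 1.000 within a handful of restarts (each a few seconds).

Diagnostics: Mdist is the minimal pairwise Euclidean distance;
`neighbor_counts` counts, per point, the others within a relative tolerance
(default 0.5%) of Mdist.  Both are O(N²) scans.

## Elastic-network normal modes

The anisotropic network model connects every atom pair within `cutoff`
(default 12 Å, appropriate for Cα/bead models) by a spring of uniform
stiffness γ (default 1; frequencies are therefore in arbitrary units, and
only mode shapes, ordering and count matter downstream).  The 3×3 Hessian
block of a contacting pair is −γ·(d dᵀ)/|d|²; diagonal blocks are minus the
row sums, making rigid translations exact zero modes.  The mass-weighted
Hessian M^{−1/2} H M^{−1/2} is diagonalized densely (scipy `eigh`); the
detected near-zero eigenpairs are discarded — six for a three-dimensional
structure, five for a linear one; more than six raises a degeneracy error
(planar or disconnected networks).  The next k eigenvectors, ascending by
eigenvalue, are labeled 7..6+k following the convention that internal modes
start after the six rigid-body modes.

Modes are stored in mass-weighted coordinates with plain unit norm: a mode
q satisfies Σ q² = 1, and the Cartesian displacement per 1 Å of MRMSD
amplitude is q_iα / √(m_i/M).  Eigenvector sign is fixed by making the
largest-magnitude component positive.  Within a degenerate eigenvalue
subspace the eigensolver's basis is returned as-is (after sign fixing);
nothing downstream depends on the particular basis.

## Hypersphere → conformation space

A hypersphere point w (|w| = 1) maps to the combined mode q_w = Σ_j w_j q_j,
which again has unit mass-weighted norm by orthonormality.  Displacing the
reference by amplitude a along q_w produces a conformation at MRMSD exactly
a, and the signed projection d_j (scalar product of the mass-weighted
displacement with q_j) recovers a·w_j.  With the mass-weighted metric the
point→conformation map is an exact isometry, so Mdist of the point set and
the minimal pairwise MRMSD of the displaced ensemble agree to machine
precision — for uniform and heterogeneous masses alike.  A plain
(unweighted) RMSD metric is also exposed, both for displacement amplitude
and for the correspondence report; with non-uniform masses it agrees with
the mass-weighted values only approximately, which is why all internal
operations default to the mass-weighted convention.

## Restrained displacement (vacuum stage)

Structures are generated along each combination vector at targets d_r =
0.1, 0.2, …, 3.0 Å (`step` = 0.1, `d_max` = 3.0 → 30 structures per vector)
by minimizing U(x) + k_mod·(d(x) − d_r)², warm-starting each step from the
previous one.  Conventions and choices:

- The restraint is k_mod·(d − d_r)² with **no ½ prefactor**; rescale k_mod
  accordingly when comparing to conventions that include it.  Default
  k_mod = 10⁴ kcal/mol/Å².
- d(x) is the signed projection onto the path's own combination vector
  (projection-only restraint); orthogonal drift is not penalized by
  default, but an optional quadratic orthogonal penalty (`k_orth`) exists.
- The minimization runs in mass-weighted coordinates y = √(m/M)·x via
  L-BFGS-B (gradient tolerance 1e-6).  This makes the null-model optimum
  move exactly along the combination vector rather than an arbitrary point
  of the d = d_r hyperplane, matching the intended "displacement along the
  given NM vector" semantics.
- The model energy U is pluggable: a null model (exact closed forms for
  testing) and a harmonic elastic-network model about the reference,
  U = ½ Δxᵀ H Δx with H the ANM Hessian.  The latter is convex, so achieved
  distances track targets to <1e-3 at the default k_mod and the model
  energy is non-decreasing along each path.

Per-step records keep target and achieved d, restraint energy, model
energy, and coordinates.  The restraining-energy surface interpolates the
scattered (d_a, d_b, E_restraint) samples of many paths linearly onto a
regular grid of a two-mode plane (scipy `griddata`); cells outside the
convex hull of the samples are NaN, and a collinear path set is rejected.
The reference itself (origin, zero energy) is included as a sample by
default.

## Ensemble metrics

The breathing (hinge) angle is the angle at the vertex center of mass of
three disjoint atom groups, clamped to [0, 180]°.  The hen-lysozyme Cα
residue ranges used for hinge characterization ship as a named preset;
generic groups are the tested surface.  RMSF superposes every frame onto
the first (Kabsch, via scipy's rotation alignment) and measures per-atom
RMS deviation from the ensemble mean — the mean-reference convention is a
package choice.  The radius of gyration is the mass-weighted RMS distance
from the center of mass.  Normal-mode-space operations never superpose
(mode displacements contain no rigid-body content); superposition exists
only in this analysis layer.

## Toy structures

The fixture generator builds connected bead models with the canonical
Cα-Cα spacing of 3.8 Å: a helical chain (α-helix-like radius 2.3 Å,
100°/bead twist, rise chosen so consecutive beads are exactly 3.8 Å
apart), a planar ring (geometric tests only — a planar elastic network is
degenerate by construction), and a helix-hinge: one helix bent ~70° about
its middle bead, so the softest elastic-network modes include hinge
bending, emulating the hinge motion of a two-domain enzyme at desk scale.
The seed applies only a global random rotation (determinism per seed,
decorrelated axes between seeds).  Masses are uniform (1 amu) or a
heterogeneous C/N/C/O pattern of standard element masses.

What the toys do *not* emulate: real force-field energetics, side chains,
solvent, anharmonicity, and the size of real proteins.  Passing tests
therefore establish the geometric and algebraic guarantees of the method
(packing optimality, isometry, restraint mechanics) — not force-field
energy surfaces or agreement with experimental ensembles, which require a
molecular-mechanics engine outside this package's scope.

## Problem sizes and defaults

Tests and the acceptance script run at desk scale: toy structures of 8–50
beads, point sets up to the 240-point 8-dimensional preset, 100-run success
statistics, 30-step restraint ladders.  These sizes were chosen to exercise
every code path and the full preset range while keeping a complete run in
minutes on one CPU.

## Known limitations

- No optimality certificates: the minimizer finds best-known packings
  empirically (restarts recommended for D ≥ 7); dimensions outside 2..8
  have no kissing presets.
- ENM eigenvalues are in spring-constant units; no cm⁻¹ frequencies.
- The restrained stage uses simplified model energies; real-force-field
  restrained minimization, solvated targeted MD, and free MD are outside
  scope.
- PDB support covers ATOM/HETATM/MODEL records at v3.3 fixed widths; no
  mmCIF or trajectory formats.
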