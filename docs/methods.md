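# Methods

This note documents the models, estimators and numerical choices behind
`loopmsm`, in the order the pipeline applies them, plus the design of the
synthetic ground-truth generator that the tests are built on.

## The synthetic system: what it emulates and what it does not

The generator emulates the statistical structure that the downstream
analysis assumes for a flexible loop sampled by many short, independently
seeded simulations:

- a **hidden Markov chain** over a few metastable conformational states
  with a known row-stochastic transition matrix `true_T` at unit frame
  lag (so stationary distribution, relaxation timescales and MFPTs have
  closed forms);
- **independent per-angle von Mises emissions** around each state's
  median (ω, φ, ψ) vector with concentration κ (κ = 0 is uniform; the
  sampler is numpy's standard rejection scheme);
- **cis states**: a state may carry ω ≈ 0° at one residue, mimicking
  cis-proline canonical clusters, which makes ω informative only for cis
  discrimination;
- **many short trajectories** with start states drawn from configurable
  seeding weights, reproducing the seeded-ensemble data regime (the
  defaults used for end-to-end validation are 89 trajectories of 2,000
  frames at 0.1 ns/frame for the 4-state system).

Angles are degrees externally, radians internally, wrapped to
[−180, 180). Terminal torsions that a real loop does not define (ω and φ
of the first residue, ψ of the last) are emitted as NaN so featurization
treats synthetic and real data identically. Per-trajectory RNG streams
derive from the master seed via `SeedSequence([seed, traj_index])`, so
ensembles are reproducible and independent of generation order.

What it deliberately does **not** model: sequence-dependent emission
statistics, correlated angles within a state, intra-state diffusive
substructure, and solvent or force-field physics. Passing tests therefore
show that the estimators recover known kinetics from data with the
assumed metastable-plus-noise structure; they are not evidence about any
specific force field or antibody.

Reference systems: `default_spec` (9-residue loop, 4 states, one cis at
residue index 6, κ = 8, slowest relaxation ≈ 67 frames),
`two_state_spec` (5 residues, switching probability 0.02) and
`three_state_spec` (7 residues, 3 states, one cis). κ = 8 gives a
circular spread of ≈ 20°, comparable to backbone torsion fluctuation
within a conformational basin and well separated from the ≥ 90° jumps
between state medians.

## Geometry

Backbone chains carry N/CA/C only; all metrics used here are
backbone-level. Torsions follow the IUPAC convention (ω(i) =
CA(i−1)–C(i−1)–N(i)–CA(i), φ(i) = C(i−1)–N(i)–CA(i)–C(i), ψ(i) =
N(i)–CA(i)–C(i)–N(i+1)). Torsion→coordinate building uses sequential
NeRF placement with fixed ideal internal coordinates (N–CA 1.458 Å, CA–C
1.525 Å, C–N 1.329 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°); with
these constants the trans CA–CA distance is 3.804 Å and the cis value
2.771 Å, both reproduced exactly by an independent trigonometric
construction in the tests. Superposition RMSD is Kabsch with the
determinant correction — proper rotations only, preserving chirality.
Superposition is loop-local (no framework anchoring); this is a
configurable convention, not a claim about how any published analysis
anchored its fits.

## Featurization and the collective variable

Each defined torsion contributes (sin θ, cos θ). Columns, never frames,
are dropped for undefined terminal angles. MSM features default to
{φ, ψ}: ω is nearly constant except across cis/trans, and the cis-bearing
synthetic system is exercised both with and without ω in the tests. The
enhanced-sampling collective variable is Σ w_sin sin ψ + w_cos cos ψ over
selected ψ angles with all-ones default weights (the combination is
standard; specific weights are a user choice).

## Well-tempered metadynamics

Dynamics are Metropolis Monte Carlo (Gaussian proposal, 5° step) on
V + V_bias over the periodic domain — engine-free, and exactly targeting
the biased Boltzmann measure. Every `stride` steps a Gaussian of height
`W₀ exp(−V_bias/((γ−1)kT))` is deposited (γ > 1). The bias is accumulated
on a fine periodic grid (1° in 1-D, 5° in 2-D) with nearest-node lookup,
keeping each step O(1) in the number of depositions; depositions are also
recorded individually. The free energy is `F = −(γ/(γ−1)) V_bias`,
min-shifted; because the converged estimator fluctuates around the true
surface, `estimate_fes(average_last=...)` can average the min-shifted
estimate over the trailing fraction of depositions, which is what the
convergence tests use (ΔF of an asymmetric double well recovered within
0.3 kT at 3·10⁵ steps). Defaults are toy units (kT = 1, W₀ = 0.5 kT,
σ = 10°, stride 500, γ = 10); physical units such as kcal/mol at 300 K
(kT = 0.5961) and large initial heights are supported by passing `kT`
and `w0` explicitly. σ has no canonical value for torsion-like CVs and
is always logged.

## Conformational clustering

Average-linkage agglomeration on a precomputed distance matrix
(Kabsch RMSD for coordinates, the circular metric below for torsions),
stopped when the minimum average inter-cluster distance exceeds the
cut-off ε; since average linkage is monotone this equals cutting the
dendrogram at ε (implementation: scipy `linkage`/`fcluster`, verified
against a brute-force O(n³) merger). ε is a required per-system
parameter — loop flexibility differs between systems and silent
auto-tuning would hide that choice; `cluster_count_curve` reports the
cluster-count-vs-ε trade-off instead. Clusters are renumbered 1..k by
descending population (ties: earlier first frame), representatives
minimise the within-cluster distance sum (ties: lowest frame index), and
transition counting never crosses trajectory boundaries. This clustering
visualises transition frequency; it feeds nothing downstream.

## tICA

Covariances are pooled over trajectories with pairs never spanning
boundaries; the time-lagged covariance is symmetrized (reversible
estimator), keeping the spectrum real. The generalized eigenproblem is
solved with a ridge `C₀ + εI`, ε = 1e−10·trace/dim, so duplicated or
nearly dependent features cannot break the solve. Eigenvalues at or above
1 in magnitude are clipped to 1 − 1e−12 for timescale computation, with a
warning. The retained dimension is the smallest d whose cumulative
squared eigenvalues reach 95% of the total (override: `dim=`). Lags are
frames internally; the pipeline converts nanoseconds via the frame
stride. A permutation bound (`noise_eigenvalue_bound`: shuffle frames
within trajectories, refit, mean + 3 std of the top |λ|) separates
genuine slow modes from sampling noise.

## Markov-state model

Microstates: k-means (k-means++ init, single fixed-seed run) in tIC
space. Counts: sliding window at lag τ, within trajectories only.
Connectivity: the largest strongly connected component of the
positive-count digraph (ties by total internal counts, then lowest state
index); frames outside the active set are excluded and the retained
state/count fractions reported, since transition probabilities are only
meaningful on a fully connected network. The reversible MLE uses the
detailed-balance fixed point
`x_ij ← (C_ij + C_ji)/(c_i/x_i + c_j/x_j)` iterated to max|Δx| < 1e−10
(cap 10⁶ sweeps), giving `T = x/rowsum` and `π = rowsum/total`; the tests
check its likelihood against an independent constrained optimizer.
Validation: implied timescales `−τ/ln|λ|` across lags, VAMP-2
(Σ λ² including the unit eigenvalue), and a Chapman–Kolmogorov test that
compares `T^k`-propagated, π-weighted set self-transition probabilities
against a model re-estimated at lag kτ.

PCCA+ uses the inner-simplex construction on the first m right
eigenvectors (computed via the symmetric similarity transform
`diag(√π) T diag(1/√π)`): normalise the trivial direction to the
constant vector, pick the row farthest from the origin in the
non-trivial coordinates, then iteratively the row farthest from the
affine span of the chosen vertices; the inverse of the vertex matrix maps
eigenvector rows to simplex corners, and memberships are clipped to ≥ 0
and row-renormalised. A degenerate eigenvalue at the m-cut raises an
error advising a different m; the number of macrostates is a user choice
guided by the eigenvalue gap (the pipeline reports the leading spectrum).
Macrostates are ordered by descending population.

MFPTs solve `(I − T_restricted) h = τ·1` with the target set absorbing;
macrostate-pair MFPTs π-weight the source members. Times are reported in
frames and physical units via the frame stride.

## Canonical-cluster mapping

Median names follow the `<loop>-<length>-[cis<positions>-]<index>`
grammar (e.g. `L3-9-cis7-1`). The assignment metric is the mean
squared-chord circular distance `2(1 − cos Δθ)` over included angles
(default {φ, ψ}; add ω to discriminate cis clusters), bounded in [0, 4],
zero iff all included angles agree mod 360°. This specific metric is this
package's choice: it is bounded, smooth and exactly testable; published
dihedral-clustering analyses do not pin down a unique formula. Frames
are assigned to the nearest median, with ties broken lexicographically
and frames beyond the assignment radius labelled unassigned. The default
radius 1.0 is half the metric's midpoint — at κ = 8 intra-state frames
lie well inside it while inter-state distances are several times larger.
A median is mapped to the macrostate of its nearest in-radius frame, else
reported unobserved. Pairs of medians hosted by one macrostate are
flagged "same kinetic minimum" with MFPT 0.

## Pipeline and determinism

All stage parameters live in a flat key=value config; every stochastic
step (generation, k-means, permutation bounds) draws from the single
master seed, and a manifest records the seed, config hash and stage
outputs. Identical config + seed gives byte-identical reports. The
conformational-clustering stage subsamples to a bounded number of frames
(default 300) before building the O(n²) distance matrix; this only
affects the visualisation stage. Problem sizes used in the validation
suite (89×2,000 frames for 4-state recovery, 60×1,500 for canonical
kinetics, 10⁵ frames for Chapman–Kolmogorov, 3·10⁵ MC steps for
metadynamics) were chosen so each check runs in seconds on one CPU while
leaving comfortable statistical margins.

## Known limitations

- The dihedral metric and assignment radius are package conventions;
  other bounded circular metrics would order assignments slightly
  differently near the radius.
- Macrostate MFPTs from a lag-τ MSM carry O(τ) discretisation bias;
  validation uses MFPTs an order of magnitude longer than τ.
- PCCA+ vertex hunting can be sensitive when eigenvalues near the m-cut
  are nearly degenerate; the estimator refuses exact degeneracy but
  near-degeneracy still warrants inspecting the eigenvalue gap report.
- The metadynamics sampler is Monte Carlo on ≤ 2 analytic CVs; it
  validates deposition semantics and free-energy reconstruction, not
  molecular dynamics.
- No Bayesian uncertainty on MSM quantities (point estimates only).
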