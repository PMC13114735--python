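# Methods

## Model and assumptions

The package studies an SIR-type rumor model with logistic growth of the
susceptible pool and quadratic (socially reinforced) incidence βSI², posed
on networks rather than continuous space: the diffusion operator is the
graph Laplacian, taken with the semi-negative-definite sign convention
L = adjacency − degree diagonal so that its eigenvalues play the role of
−k² wavenumbers.  Nodes are internally homogeneous populations (a forum,
a platform, a community); edges are contact channels.  All kinetic rates
are per unit time; densities are dimensionless fractions of a reference
population, so the carrying capacity K and equilibrium values are O(1).

Heterogeneity enters through per-edge permissions: each edge carries a
non-empty subset of {S, I, R} naming the compartments that may cross it
(seven classes, the conventional color code being red={S}, green={I},
blue={R}, yellow={S,I}, magenta={S,R}, cyan={I,R}, black={S,I,R}).
Decomposition by class yields three layer Laplacians A, B, C.  Layers are
unweighted and undirected; weighted, directed and temporal networks are
out of scope.

## Network generators

* Lattices: degree-4 (von-Neumann), degree-6 (von-Neumann plus the
  (+1,+1) diagonal pair) and degree-8 (Moore) neighborhoods.  Boundary
  handling defaults to periodic (toroidal), so every node has exactly the
  nominal degree and the degree-4 spectrum has the closed cosine form used
  in tests; open boundaries are available.  The degree-6 construction is
  one of several consistent conventions and is configurable in principle
  by editing the offset table.
* Erdős–Rényi G(n, p) and Barabási–Albert preferential attachment, via
  networkx.  The BA seed graph is a complete graph on m nodes, so the edge
  count is exactly C(m,2) + (n−m)m.  ER samples may be disconnected; the
  package warns and reports the component count rather than resampling,
  because the spectral-bound analysis does not require connectivity (only
  the graph-Fourier homogeneity argument does).
* Permission assignment is i.i.d. per edge, either uniform over the seven
  classes or from user-supplied class fractions; one integer seed per
  generator call makes every artifact reproducible.
* Edge lists are tab-separated `u v TOKEN` with 0-based indices, `#`
  comments and an `n_nodes=` header; round trips are bit-exact.

## Equilibrium theory

Eliminating S = (μ2+α)/(βI) and R = αI/μ3 from the steady-state equations
gives the depressed cubic f(I) = Kβ²I³ + Kβ(μ1−r)I + r(μ2+α).  Since
f(0) > 0, positive equilibria require μ1 < r and f < 0 at the positive
critical point I″ = sqrt((r−μ1)/(3β)); then exactly two positive roots
exist (branches `lower` < `upper`).  Roots come from the numpy companion
matrix and are polished by four Newton steps; complex roots are discarded
at |Im| > 1e-9·max(1,|Re|); an exact tangency f(I″)=0 is returned as a
single equilibrium flagged `degenerate`.  Every stability routine
validates that its equilibrium argument actually zeroes the cubic before
proceeding, because all downstream identities (J₁₁ = −rS*/K, the
simplified dispersion coefficients, the fixed-point property of the
simulator) hold only at true equilibria.  Branch choice is always an
explicit argument — at the pattern-formation preset only the upper branch
satisfies H1, but that is a property of the parameters, not a default.

## Stability criteria

* H1 (homogeneous perturbations): μ2+α−rS*/K < 0 and 2r−3rS*/K−2μ1 > 0,
  both strict, with margins reported.  The full cubic Routh–Hurwitz test
  (a1 > 0, a3 > 0, a1a2 > a3) is implemented independently as an oracle;
  the test suite surveys random equilibria for disagreement between the
  two and requires at minimum that H1 implies the full criterion.
* Homogeneous networks: per-mode quadratics λ² + u(η)λ + v(η).  Both the
  raw coefficient forms (from the explicit Jacobian entries) and the
  simplified forms (after the equilibrium identities) are evaluated and
  must agree to 1e-8, which catches transcription and input errors.  The
  unstable interval (η1*, η2*) comes from the quadratic formula on the
  coefficients of v; Turing capability additionally requires H1 and a
  network eigenvalue strictly inside the interval.
* Heterogeneous networks: the spectral bound φ is the sum of the exact
  2-norms of the block-diagonal part (symmetric blocks, so the max
  absolute eigenvalue over the three layers) and the constant off-diagonal
  reaction block, whose Gram matrix is diagonal, giving
  max{βI*², sqrt(4(μ2+α)²+α²)} exactly.  A variant without the square
  root on the second candidate is also computed for comparison; it is not
  a valid norm bound and the property suite (φ ≥ spectral radius of the
  dense Jacobian on random instances) holds for the radical form.
  Conditions H2 and H3 are mode-wise first-order conditions in the
  eigenvalues θ_m of the S-layer: H2 needs a mode with
  d1θ_m + r − 2rS*/K − μ1 > 0 (the b1 > 0 branch), H3 covers the
  complementary b1 < 0 branch and then requires b2 > 0 at that mode.  Both
  branch readings are itemized in the report.  These conditions are
  necessary, not sufficient; the simulation suite checks necessity (no
  pattern-forming run with both false) and makes no sufficiency claim.
* The ground truth for all of the above is the dense 3N×3N Jacobian,
  assembled blockwise and solved with a general (non-symmetric)
  eigensolver; symmetric Laplacians use symmetric solvers throughout.
  Dense solves are capped at N = 2000 by default.

## Time integration

Explicit forward Euler on sparse (CSR) Laplacians.  Default dt = 1e-3; a
warning fires when dt exceeds the diffusion stability ceiling estimated by
Gershgorin (2 / max_layer d·2·maxdegree).  The large pattern runs use
dt = 0.02, 80% of the exact ceiling 2/(d1·8) = 0.025 on the degree-4
torus.  Large-amplitude heterogeneous patterns (node values ~18) tighten
the ceiling through the reaction term βI²; the sweep drivers halve dt and
retry on divergence.  Euler undershoot below zero is clipped at 0 with a
logged count (steady states of interest are interior; clipping was never
observed in the shipped experiments).  Steady-state detection is
residual-based — max-norm of the full right-hand side below tolerance —
so the criterion does not depend on dt.  Snapshots are stored every
`stride` steps plus the final state.

The initial condition for pattern experiments is the equilibrium times
node-wise (1 + U(−a, a)) with amplitude a = 0.01 and a fixed seed; runs
continue until the residual falls below 1e-7, which on the 32×32 torus
happens near t ≈ 5·10⁴ (the final approach to the saturated pattern is
governed by a slow stable mode of order 1e-4).

## Graph Fourier analysis

Node fields are decomposed in the orthonormal Laplacian eigenbasis,
eigenvalues sorted descending so index 0 is the zero mode; on connected
graphs that eigenvector is fixed to the positive constant vector.
Round-trip and Parseval identities hold to 1e-10.  Lattice spectra are
highly degenerate and individual eigenvectors within a multiplet are
solver-dependent, so quantitative statements use per-eigenvalue summed
squared coefficients, which are rotation-invariant.  Scatter outputs
follow the display convention (−η on the abscissa, log2|k| on the
ordinate) with a default floor of 2⁻¹⁸; the homogeneity criterion (only
the constant mode loaded) is asserted only for connected graphs.

## Calibration stage

With spatially flat initial data and zero-flux boundaries the diffusion
terms vanish identically, so fitting a single aggregate participation
series uses the 4-ODE reduction with cumulative adoption N' = βSI².  The
forward model integrates with classical fixed-step RK4 (the system is
smooth and non-stiff; fourth order lets the optimizer loop run at
dt = 0.1 with discretization error far below the observation noise),
shortening the last sub-step to land exactly on grid times.

The synthetic-series generator emulates a daily, pre-aggregated,
noise-corrupted cumulative participation fraction over a 54-day window:
model N(t) plus i.i.d. Gaussian noise of sd 0.005, clipped at zero,
started from (S, I, R, N)(0) = (1, 0.1, 0.1, 0.002).  It reproduces the
S-shaped growth and jitter of such series but not their reporting
artifacts (weekday cycles, retroactive corrections, heteroscedastic
volume-dependent noise), so passing calibration tests demonstrates
correctness of the machinery, not robustness to real-data pathologies.

Fitting is a greedy random walk over the seven kinetic rates:
multiplicative log-normal proposals (5% scale) clipped to box bounds,
accepted only when the sum of squared errors on N(t) decreases; the
best-so-far trace is non-increasing by construction and the whole
procedure is deterministic under its seed.  S, I, R are latent; only N is
scored.  Hyperparameters (4000 iterations, 5 restart seeds, bounds) are
package choices.

**Identifiability.**  R feeds back into no other equation, so N(t)
carries no information about μ3 at all and constrains μ2 and α only
through their sum: the α/μ2 split is structurally unidentifiable from a
cumulative series (the corresponding Fisher eigenvalue is numerically
zero).  At the shipped calibrated preset, log β also trades against log K
along a sloppy direction with linearized standard deviation above 100% at
noise 0.005 and 54 points.  Consequently the quantities this stage can
genuinely recover are the replacement sum μ2+α (a few percent in
practice), the curve-level fit quality (RMSE at the noise floor), and the
well-constrained combinations of (K, β, μ2+α); per-parameter recovery of
α — and reliably of β — from a single cumulative series should not be
expected, and the test suite states this expectation explicitly rather
than hiding it.  The calibrated demonstration preset (r=4.2125, K=0.9938,
β=0.9996, μ1=0.0045, μ2=0.0654, μ3=0.5481, α=0.0369), derived from a
2020 Indonesian COVID-19 rumor wave, is shipped for demonstrations and as
the default synthetic-truth, not as a test target.

The intervention experiment switches α to a boosted value at t = 30
(a debunking campaign) and compares cumulative curves; final N is
non-increasing in the boost level.

## Problem sizes in the shipped experiments

Lattice experiments use the 32×32 torus (N = 1024); oracle sweeps use
random connected graphs with N ≤ 20 (block reduction, 100 instances) and
N ≤ 30 (spectral bound, 50 instances); the heterogeneous necessity sweep
runs 20 three-layer configurations (lattice/ER/BA, N = 64–100, five
permission schemes) to t = 300.  These sizes are the package's own
choices — the qualitative phenomena are size-stable well below them.

## Known limitations

* Sufficient conditions for heterogeneous-network Turing instability are
  not available (only necessity is checked); no amplitude equations or
  weakly nonlinear analysis.
* Explicit Euler is first-order; steady-state *locations* are accurate
  (residual-based convergence) but transient paths carry O(dt) error.
* Pattern morphology is characterized only through heterogeneity
  statistics and spectral mass, not through shape classification.
* The calibration stage fits the spatially homogeneous reduction; a
  network-resolved fit is out of scope.
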