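# Methods

## Model

A connected undirected network on N nodes with weights w_ij ≥ 0 hosts the
donation game under death-birth updating: the dying node i is uniform; the
reproducing neighbor j is drawn with probability ∝ w_ij R_j, where
R_j = 1 + η f_j and f_j = −c x_j + b Σ_l p_jl x_l is the neighbor-averaged
payoff (x is the cooperator indicator, p_jl = w_jl/s_j the random-walk
step, s_j the node strength). At η = 0 the process is the voter model; the
per-start fixation probability then equals the stationary distribution π,
which the exact oracle verifies numerically.

Weak selection gives the first-order fixation probability
ρ_C = 1/N + (η/2N)[−c τ₂ + b(τ₃ − τ₁)] + O(η²) and hence the threshold
(b/c)* = τ₂/(τ₃ − τ₁), with τ_k = π (P^k ∘ T) 1 and T the pairwise mean
coalescence times of the two-walker process in which one walker (chosen
with probability ½) moves per step.

Sign conventions worth stating once: a *positive* slope Δ(b/c)* for an
edge means increasing that edge's weight raises the threshold (hinders
cooperation); removal (ε = −1) of a high-slope edge therefore lowers it.
(b/c)* can be negative (τ₂ and τ₃ − τ₁ of opposite sign) — cooperation is
then never favored at any positive ratio — or infinite when τ₃ = τ₁
(e.g. the 4-cycle). Both cases are reported with an explicit
`degenerate`/sign rather than NaN, and per-edge slopes are refused on a
degenerate base network.

The payoff convention: each player acts as donor and recipient equally
often, and f is the neighbor-averaged payoff above. Any global factor in f
rescales η only and cancels in (b/c)*, so the threshold and slope are
convention-independent; only the η-scale of ρ_C depends on it.

## Solving the coalescence system

Off the diagonal, the defining recurrence is the Lyapunov-type matrix
equation

    T − (P T + T Pᵀ)/2 = 1 1ᵀ − diag(c),

where diag(c) collects the (unknown) diagonal slack created by enforcing
t_ii = 0. P = D⁻¹W is similar to the symmetric A = D^{−1/2} W D^{−1/2} =
U Λ Uᵀ, so the substitution T = D^{−1/2} U X Uᵀ D^{−1/2} diagonalizes the
operator into entrywise factors 1 − (λ_a + λ_b)/2. Exactly one factor
vanishes — the Perron pair (λ = 1), whose kernel direction is 1 1ᵀ/S. The
N unknowns c, plus the kernel coefficient α, are pinned by the N
constraints t_ii = 0 and the solvability condition sᵀ(1 1ᵀ − diag(c))s = 0.
Their (N+1)×(N+1) coefficient matrix is independent of the right-hand
side, so it is LU-factorized once per network; every subsequent solve
(the base T, and each per-edge ΔT) costs four dense N×N products.

Why not sparse LU, which a first design suggested: the pair system couples
pair (i,j) to all pairs (j,k), k ~ i, and (i,k), k ~ j; its elimination
graph fills in catastrophically (measured ≈ 20 s per factorization at
N = 100 with SuperLU, versus ≈ 30 ms for the spectral route). The compact
sparse-LU path is retained (`coalescence_times(..., method="compact")`)
and tested to agree with the spectral solution to 1e−10, as is the
explicit sparse redundant system M(0) vec(T) = d over ordered pairs, which
the dense oracles in the tests assemble and invert directly.

Numerical safeguards: the Perron eigenvalue must be simple (otherwise the
network is disconnected and rejected earlier); the residual of the
defining recurrence is checked below 1e−9 in max norm and all off-diagonal
t_ij ≥ 1 are asserted after every solve. Near-singular factors occur only
when λ₂ → 1 (nearly disconnected networks), where the problem itself is
ill-conditioned; the residual check converts silent inaccuracy into an
explicit error.

## Perturbation pipeline

For a weight change ε on edge (i₀, j₀): Δπ has the closed form
(δ_{i,i₀}+δ_{i,j₀})/S − 2π_i/S. Θ⁽¹⁾ has only rows i₀ and j₀ nonzero;
Θ⁽²⁾ and Θ⁽³⁾ are implemented both entrywise and as product-rule
compositions (Θ⁽¹⁾P + PΘ⁽¹⁾, etc.), cross-checked to 1e−10. The
derivative ΔM of the redundant system has entries −θ⁽¹⁾_ik/2 at
(row (i,j), column (j,k)) and −θ⁽¹⁾_jk/2 at (row (i,j), column (i,k)), so
its action on vec(T) is the symmetrized matrix −(Θ⁽¹⁾T + (Θ⁽¹⁾T)ᵀ)/2 with
zero diagonal — O(N²) because Θ⁽¹⁾ has two rows. Exactly 4N−6 ordered-pair
rows are structurally nonzero (rows touching i₀ or j₀); structural means
pattern, not value — the derivative row of a leaf node cancels numerically
(its single transition probability is pinned at 1) but is still stored.
ΔT solves M(0) vec(ΔT) = −ΔM vec(T(0)) through the retained spectral
decomposition; Γ_k = Δπ(P^k∘T)1 + π(Θ⁽ᵏ⁾∘T)1 + π(P^k∘ΔT)1; the slope
follows by the quotient rule. Self-loop perturbations (i₀ = j₀) are
rejected — the strength bookkeeping for a self-loop differs and is not
needed by any experiment.

Validation is by central finite differences of the fully recomputed
quantities at h = 1e−3 and 1e−4 (residuals must decay as O(h²)) and by a
dense linear-algebra oracle that assembles M(0) and ΔM explicitly at
N ≤ 12.

## Synthetic networks (the stated world)

Defaults reproduce the experimental setup: ER with N = 100 and exactly 300
uniformly chosen edges; BA grown from a 4-node star with m = 3 (exactly
291 edges at N = 100, 891 at N = 300); planted 2-partition with p_in =
0.11, p_out = 0.01 (theoretical mean degree 5.89); LFR-style benchmark
with degree exponent γ = 3, community-size exponent κ = 2, mean degree 6,
k_max = 100, mixing 0.1. Random models are rejection-sampled whole until
connected, with the retry count recorded in the generator metadata.

The LFR generator is built in-package because the established
implementation (networkx) does not converge for κ = 2 at these sizes: the
degree cutoff is bisected so the expected mean degree hits the target,
community sizes are power-law draws summed to N, each node splits its
stubs (1−μ̄) internal / μ̄ external, and stubs are matched into a simple
graph with unmatchable leftovers dropped. Realizations are additionally
required to have ≥ 2 communities and a mean degree within ±1 of target.
Consequences for interpretation: realized mixing tracks μ̄ only to a few
percent and degree sequences are approximate, so green LFR tests establish
class-level behavior (community structure with the stated exponents), not
exact equivalence with any particular published LFR code.

Removal-mode experiments (correlations, greedy surgery) are defined only
on networks where every edge is removable; bridges would disconnect the
graph and leave (b/c)* undefined. Bridges are therefore excluded from
candidate sets with a logged count, and the experiment drivers can select
bridge-free instances outright (`surgery.bridgeless_instance`) — the
setting of the published per-network analyses, whose correlation sample
sizes equal their edge counts. This matters quantitatively: planted-
partition instances containing bridges correlate visibly worse (mean r ≈
−0.74 vs ≈ −0.81 bridge-free over 12 seeds).

What a green correlation test does *not* establish: equality with any
single published instance. Regenerated ER instances, for example, span
r ≈ −0.73 … −0.88 over seeds; the acceptance script therefore averages
over five instances and reports the ensemble-mean correlation.

## Evolutionary-dynamics validators

The exact oracle builds the full 2^N absorbing Markov chain (capped at
N = 14), with self-transition mass accounted explicitly, and solves the
absorption probabilities into the all-cooperator state sparsely. The
Monte-Carlo estimator gives each replicate its own counter-derived RNG
substream, so estimates are reproducible and order-independent. Selection
strengths are guarded by 1 + η f > 0 (f ∈ [−c, b]); larger η raises an
error advising a smaller value rather than producing negative rates.

## Other numerical choices

- Greedy removal ties: slopes within 1e−9 (relative to the max) are tied;
  the lexicographically smallest pair wins, making trajectories on
  vertex-transitive graphs deterministic.
- Degree-sum heuristic ties: all tie-resolution branches are enumerated
  breadth-first, subsampled with a seeded RNG beyond 64 branches.
- ε-sweep default grid: 0.1 spacing over the mode's admissible range;
  the chord-deviation statistic quantifies nonlinearity (enhancement
  responses are near-linear, removal responses are not).
- Floats in CLI output are emitted at 12 significant digits; all
  stochastic commands take explicit seeds.

## Known limitations

- Fixation beyond first order in η is available only through the 2^N
  oracle (N ≤ 14) or Monte Carlo; no closed form at finite η.
- Directed, signed, or multi-edge networks are out of scope; self-loop
  perturbation is unsupported (self-loops are representable in the
  container).
- The addition-mode correlation is weak (as in the underlying theory's
  published behavior) — the slope at ε = 0 is a poor predictor of the
  effect of adding a whole unweighted edge; the package computes it but
  no acceptance-grade claim is made.
- The per-edge slope is O(N²)-after-precompute in this implementation only
  because the constraint matrix is shared; total memory is O(N²) per
  workspace, fine to N ≈ 1000, untested beyond.
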