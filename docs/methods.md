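# Methods

## Model and scope

`boolpop` simulates populations of **non-interacting** individuals, each an
instance of a Boolean network with N variables updated synchronously. The
state of an individual is a subset κ of ON variables; a population is a
weight vector w over states with normalisation W = Σ w = 1 throughout (W is
carried as metadata only, never varied). The package tracks product-basis
moments ⟨x_α⟩ — the population fraction with all variables of α ON — which
carry strictly more information than marginal means: co-occurrence moments
encode correlations (two variables each at level 0.5 can co-occur anywhere
in [0, 0.5]).

Out of scope by design: interacting cells, division/death and population
size dynamics; gain-of-function or per-edge wild-type augmentation;
equation-factorisation schemes for long-term attractor extraction.

## The engine

**Single rules.** For variable i with inputs θ^[i] and output vector k^[i]
(one entry per input subset, canonical order: cardinality, then
lexicographic on sorted global indices), the update is
f_i = k^[i]·T⁻¹·x^[i]. The coefficient of x_κ is the subset-Möbius
transform Σ_{α⊆κ} (−1)^{|κ|−|α|} k_α, computed by the in-place O(n·2ⁿ)
transform; the explicit T and T⁻¹ matrices exist only for inspection and
small-n validation. Coefficients are exact Python integers for
deterministic rules.

**Multi-index rules.** Discrete time: f_{ij…} = f_i·f_j·…, distributed and
reduced with x_β·x_γ = x_{β∪γ} (idempotence of Boolean variables); products
are taken smallest-factor-first and like terms merged as dictionaries keyed
by subset bitmask. Continuous time: the product rule of derivatives,
f_{ij…} = Σ_m x_{rest}·f_m, reduced the same way. The empty subset carries
f_∅ = x_∅ (discrete) or f_∅ = 0 (continuous).

**Closure.** A FIFO worklist starts from Ω₀ (the empty subset is always
included), solves each pending subset, and enqueues every newly referenced
subset in canonical order; this makes the Ω ordering, and hence the operator
layout, reproducible run to run. Termination is guaranteed (Ω ⊆ 2^θ is
finite and never shrinks) and asserted on every run. Two loud failure modes
guard the exponential worst case the method admits: a per-rule input cap
(default 20 inputs, i.e. 2²⁰ table entries) and an |Ω| cap (default 10⁶)
whose violation reports the size reached and the unsolved frontier.
Only subsets appearing with nonzero coefficient after reduction are counted
in Ω; a convention that counts cancelled subsets would report larger
dimensions for the same system.

**Arithmetic.** Deterministic networks stay in exact integer arithmetic end
to end: rules have integer coefficients, the operator gets an int64 sparse
twin, and populations with rational weights can be evolved as `Fraction`
vectors (or, for the uniform mixture, as integer vectors scaled by W = 2^N).
Probabilistic and continuous-time rules use floats with a 1e-12 drop
tolerance applied when merging terms, so cancellations that are exact in the
algebra produce true structural zeros rather than phantom subsets.

## Probabilistic, asynchronous, and continuous time

For probabilistic networks k^[i] holds ON-likelihoods. The same algebra
yields equations that close only in the infinite-population limit (the
per-individual reading has p(x) on the left and x on the right), so the
engine's output is the exact large-population mean; individuals remain
stochastic and are handled by the Monte Carlo module. Rate augmentation
f'_i = (1−r_i)x_i + r_i·f_i is implemented as a likelihood table over
θ^[i] ∪ {i}; r_i = 1 recovers the deterministic rule, r_i = 0 freezes the
variable. Asynchronous networks are supported only through this mapping —
per-step update probabilities r_i = rate_i·Δt with a user-chosen small Δt —
and the O(Δt) approximation is inherent to that prescription.

Continuous time treats an individual as a Markov jump process: variable i
flips toward its logic target g_i(state) at rate r_i whenever they disagree.
The single-variable rate is therefore f_i = r_i·(g_i − x_i), the unique
continuous limit of the rate-blended discrete update
((f'_i − x_i)/Δt with r_i → r_i·Δt); with unit rates the coefficients stay
integer. This derivation of f_i from the logic rule is a design choice of
this package: the differential formalism fixes only the product rule for
higher moments, not the single-variable rates. Integration uses DOP853 with
rtol = tol (default 1e-8, 1e-10 in validation) and atol = tol·1e-3;
⟨x_∅⟩ = 1 is conserved to within the tolerance and checked in tests.

## Populations

Initial moment vectors come from four specs: `uniform` (p = 1/2 i.i.d.),
`marginals` (independent per-variable p_i, moments Π p_i), `explicit`
(weighted state list, weights must sum to 1 within 1e-12, moments
Σ w_s·[α⊆s]), and `knockout`. The knockout spec applies to a
wild-type-augmented network (companion variables named `gene.WT`, constant
self-copy rules, ANDed into their gene's rule): each companion is ON with
probability 1−μ; the gene follows its activation marginal when the companion
is ON and is pinned OFF otherwise. Moments are products of per-gene factors
— ⟨x_α⟩ multiplies (1−μ)·p_g for each gene in α and (1−μ) for each bare
companion — so building the initial state never enumerates the mutational
profiles; this factorisation is what makes populations with ~2^N profiles
tractable. μ = 10⁻⁴ per gene (the default in examples) corresponds to a
homozygous loss-of-function rate of 0.01%.

## Oracles and the synthetic-network generator

Validation is dual-route throughout: the product-basis engine is compared
against independent implementations that never touch the closure algebra.

* **State-space oracle** (N ≤ 12, enforced): evolves the full 2^N weight
  vector — successor-table scatter for deterministic networks (exact in
  integer/rational arithmetic), dense column-stochastic transition matrix
  for probabilistic ones (N ≤ 10), dense jump-process generator integrated
  with DOP853 for continuous time — and reads off all moments with a
  superset-zeta transform.
* **Monte Carlo**: vectorised sampling of initial states from any population
  spec and synchronous per-variable updates (independent likelihood draws
  for probabilistic rules); standard errors scale as 1/√n_runs, and the
  continuous-time sampler is the small-Δt probabilistic limit with the
  largest per-step probability capped at 0.05.
* A second, structurally different closure oracle in the test suite derives
  each multi-index rule from the joint truth table over the union of the
  members' inputs and runs its own fixpoint, confirming the product-based
  closure rule by rule.

Random test networks stand in for external models: each variable draws its
in-degree uniformly from 1–4, picks distinct inputs, and fills its truth
table with fair coin flips (~25 edges at N = 10). Self-inputs are allowed
and truth tables may ignore an input; both behaviours can be disabled by
generator flags (`allow_self_inputs`, `allow_degenerate`), and the choice is
recorded in the network's provenance metadata. These ensembles probe the
algebra uniformly over random logic; they do not emulate the degree
distributions, canalising rules, or modularity of curated biological
networks, so passing them certifies correctness of the machinery, not
biological realism.

Validation campaign sizes (200 deterministic networks × 30 steps, 100
probabilistic networks against 10⁴-run Monte Carlo plus 25 against the
N = 8 master equation, 25 continuous networks at sup-norm 1e-6) are chosen
so the full suite replays in well under a minute while the deterministic
comparison remains *exact equality* over every tracked moment and time —
a stronger check per network than a sampling comparison.

## The ladder fixture and the knockout screen

`ladder6.bnet` is a 6-node feedforward toy: a self-sustaining input IN
drives two marker branches and a delayed inhibitor INH that shuts both
outputs OA, OB off, so wild-type co-activation of the outputs is transient.
After full wild-type augmentation (12 variables — small enough for the
exact oracle) and a μ = 10⁻⁴ knockout population, a rare subpopulation with
INH lost keeps OA∧OB ON permanently at the factor-model level
0.5·μ·(1−μ)⁵ ≈ 0.005%, while the three-way series OA∧OB∧INH.WT drops to
exactly zero — demonstrating, at fixture scale, how the engine proves a
specific loss necessary for a phenotype with no sampling error. Larger
published models (e.g. T-cell receptor logic) are used by transcribing
their rule tables into the same file format; the package ships no such
transcription.

## Known limitations

* Closure can be exponential: dense feedback topologies drive |Ω| toward
  2^N, and the caps exist to fail loudly rather than thrash. Feedforward
  structure is the favourable case.
* Probabilistic results are population means only; no per-individual
  stochastic trajectories in the product basis.
* The asynchronous mapping is first-order in Δt by construction.
* Float closure (probabilistic/continuous) relies on the 1e-12 drop
  tolerance to recognise exact cancellations; likelihoods within 1e-12 of
  each other can in principle misclassify a term as zero.
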