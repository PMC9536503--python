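# Methods

## Model and conventions

A model is the tuple (S, v_lb, v_ub, growth reaction). Exchange reactions
are detected as columns with exactly one nonzero stoichiometric entry and
follow the convention *negative flux = uptake*. All bounds are clamped
into a ±10,000 flux box on loading, so the indicator constant M = 20,000
(double the box) is always valid; the validator rejects models where that
cannot be arranged.

Applying an environment (nutrient set N, inhibited set I) blocks uptake of
every exchange outside N, zeroes reactions in I, and never relaxes
secretion bounds. Two modes exist deliberately:

* **plain mode** (`forced_uptake=False`) for FBA/FVA growth screening and
  wild-type ranges — nutrients are *available* (lower bound −1000);
* **forced-uptake mode** for evolved states and couplings — every
  component must also be *consumed* (upper bound −1), since the evolved
  state is defined as growth synthesized from all environment components.

## Wild-type ranges

Wild-type flux ranges are FVA ranges in the reference (application)
environment with growth fixed at `growth_fraction` of its maximum
(default 1.0 — the fully fit phenotype; exposed because the choice changes
basis content). Thresholds add a multiplicative slack δ (default 0.03) and
an absolute floor ε (default 1e−6): the floor keeps zero-flux ranges from
being infinitely strict, the default δ is a small allowance for flux
variability. The worked examples and tests use δ=0, ε=1e−6 so every
expected value can be derived by hand.

## Flux-basis MILP

One binary per candidate reaction gates its flux into the wild-type
thresholds using the exact bound gaps as coefficients
(`v_i − y_i(v_ub,i − w_ub,i) ≤ w_ub,i`, and symmetrically below), so no
big-M is needed here. Reactions whose bounds already fit inside the
thresholds get no binary (they cannot deviate), and reactions in
`exclude_from_basis` deviate freely at zero cost — the default examples
exclude the growth reaction, treating growth as fitness rather than as
part of the trait, but the exclusion set is empty by default so users can
make either reading explicit.

Alternative optima are enumerated by re-solving with the integer cut
`Σ_{j∈previous} y_j ≤ n − 1` until the objective exceeds the minimum
cardinality n or the enumeration limit is hit (flagged as truncated).
Directions: a member is *up* if the trait level is attainable only with
its flux strictly above the upper threshold (one-sided feasibility probe
with all non-members confined and other members free), *down* in the
mirror case; members feasible on both sides are resolved by the witness
solution and flagged ambiguous. The probe offset is 10× the feasibility
tolerance.

## Evolved state and couplings

The evolved state minimizes total nutrient uptake `Σ_n (−v_n)` at fixed
growth flux `v_mu = growth_norm` (default 10 — the "arbitrary unit of
growth" that normalizes all scores across growth rates). Downstream
problems hold total uptake at this optimum within the feasibility
tolerance. The alternative, taking the printed inequality direction
`c·v ≥ r_uptake,max` literally (which is non-binding at a minimum), is
available via `uptake_rule="literal"` but off by default; the binding
interpretation is the one under which couplings measure what evolution at
maximal nutrient efficiency forces.

An up-member's coupling is the minimum attainable |v| under those
constraints (how much flux growth *forces*), a down-member's the maximum
attainable |v| (how little growth *allows*). Minimized absolute values are
linearized with two inequalities (`t ≥ ±v`); maximized ones need one
indicator binary selecting the sign branch (`t ≤ v + M·d`,
`t ≤ −v + M(1−d)`). Exactness of the linearization at every optimum is
recorded (`linearization_gap`) and asserted to 1e−6 in the tests. The
worst-case total response `s_min` comes from one joint MILP; per-member
couplings are recomputed by individual optimizations because the joint
optimum need not be unique per coordinate. Members with coupling above
`coupling_tol` (1e−6 in growth-normalized flux units) form the tacking
trait.

The coverage MILP gives each member a binary that, when zero, forces its
coupling within `(1+γ)` (up) resp. `(1−γ)` (down) of its reference-
environment coupling while total response is held at `s_min`; minimizing
the binaries yields `b_min`, the worst-case count of members selected more
strongly than in the reference. Default γ = 0: strictly
stronger-than-reference. Reference couplings are computed with the same
per-member operations under the reference environment's evolved state; the
reference may be the application environment or any laboratory condition.
On numerical infeasibility at `s_min` the solve is retried once with 10×
slack and flagged `relaxed`.

## Score and ranking

`score = 10³·(k − s_min)/(k+l) + 10³·(k+l − b_min)/(k+l) + z`, evaluated
literally, no clamping — a negative `s_min` (selection against the basis)
legitimately inflates the score. The component count z discounts
environments whose many ingredients make the organism's nutritional
response less certain. Ranking sorts ascending by score with
deterministic tie-breaks (fewer components, then label); non-growth-
supporting environments are listed last, unscored. When several minimal
bases exist each is scored and the environment keeps its best score, with
the basis index recorded. Enumeration supports exactly-k and up-to-k
nutrient combinations (the bundled replication preset uses exactly 3,
which gives C(22,3) = 1,540 candidates from a 22-nutrient catalogue) and
an optional cross-product with single inhibitors.

## Solver determinism

All LPs and MILPs go through one backend class wrapping scipy's HiGHS
interface: fixed variable and constraint insertion order, single thread,
no random restarts — reruns are bit-identical, and ranking TSVs are
byte-identical. MILP integrality is read back with a 0.5 threshold on the
binaries; every reported quantity is an objective value or a per-flux
optimum, never an arbitrary vertex of a degenerate face.

## Synthetic data

The toy networks are designed so every expected number is a hand
mass-balance: TOY1's nutrient B co-produces the product with growth
(coupling 10 at `v_mu` = 10), nutrient A allows a complete bypass
(coupling 0). SERIES and PARALLEL isolate full coupling and redundancy.
The seeded random-network generator builds a guaranteed-feasible
nutrient→growth chain plus a product branch, an optional second nutrient
and up to two random (possibly reversible) internal reactions, capped at
12 reactions so the exhaustive oracles stay tractable. These fixtures
exercise the combinatorics of small networks exhaustively; they do not
emulate genome-scale features — cofactor cycles, compartments,
maintenance ATP, thousands of alternate optima — so passing tests
demonstrate algorithmic correctness, not biological accuracy of any
particular genome-scale prediction.

The oracles (exhaustive subset sweep for the basis, sign-split LPs for
coupling classification, full flag/sign enumeration for `b_min`) assemble
their LPs directly with `scipy.optimize.linprog`, sharing no constraint-
building code with the production MILPs.

## Growth curves

The signal is log-transformed and fitted with an order-3 smoothing
spline. The smoothing factor defaults to `n·σ̂²` with σ̂ estimated
robustly from second differences (so noiseless data are interpolated);
it is exposed as a parameter. `mu_max` is the maximum spline derivative;
`max_level` the maximum of exp(spline). The lag is the first time, after
the smoothed curve has passed its minimum, at which the smoothed signal
reaches `threshold_fraction` (0.10, or 0.25 for slow-starting profiles;
never switched silently) of the maximum level. The threshold is applied
on the signal scale, which makes `mu_max` and lag invariant to rescaling
the signal — the property that pins down this reading of the threshold.
The lag estimate is informative only when the curve rises above
`1/threshold_fraction` times its baseline; the synthetic delayed-growth
fixtures are constructed in that regime and recover the programmed lag
within one sampling interval.

## Problem sizes

Tests and the acceptance script run on the toy fixtures (≤ 8 reactions),
50 seeded random networks (≤ 12 reactions) for three-way oracle
equivalence, and 20 random networks inside the acceptance sweep — sizes
at which the exhaustive oracles are exact and the whole pipeline
completes in seconds. Genome-scale models are supported through the same
API (dense S; SBML via cobrapy) but carry no bundled fixture.

## Known limitations

* Flux couplings are evaluated only against growth, not as a full
  pairwise coupling matrix.
* No gene–protein–reaction mapping: bases are reaction-level.
* The evolved-state proxy (minimal uptake at fixed growth) is a
  stationary endpoint model; trajectories, clonal interference and
  covariance changes during evolution are out of scope.
* Feasibility of top-ranked environments is model-based only; literature
  or experimental screening of the shortlist remains the user's step.
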