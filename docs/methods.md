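# Methods

## Dynamical model

The core object is a weighted-sum Boolean network: binary node states
`s_i`, integer basal levels `b_i`, nonzero integer link weights `w_ij`, and
the synchronous update `s_i(t+1) = [Σ_j w_ij s_j(t) + b_i > 0]`. The
threshold comparison is strict by default so that a node with zero net input
and zero basal level rests OFF; `SimulationConfig(strict_threshold=False)`
switches to `>=` for sensitivity checks. Updates are synchronous throughout;
asynchronous and continuous dynamics are out of scope.

Per update step the order of precedence is: weighted sums first, then the
`A` (force 1) and `I` (force 0) status clamps, then scenario input clamps,
and finally drug suppression, which forces a suppressed node to 0 and a
suppressed link's contribution to 0 and therefore wins over every clamp.
The only consequential choice here is suppression-beats-`A`: a dose-1 drug
on a constitutively activated node silences it, which is what "full
inhibition of the target" means.

Trajectories run `transient_steps` (default 100) discarded updates followed
by `steady_steps` (default 100) recorded ones; *activity* is the per-node
mean over the recorded window, and a trajectory is scored *cell death* when
the death readout's activity exceeds `death_threshold` (default 0.9, i.e. a
sustained, not pulsatile, caspase signal). The fixed averaging window (not
attractor detection) is used deliberately: it is insensitive to cycle
length, and a window of 100 averages any cycle of even period exactly.

State enumeration runs over the *free* nodes (input-dependent and not a
scenario input) in declared node order, binary counting with the first free
node as the most significant bit. Exhaustive enumeration is used up to
`enumeration_cap = 22` free nodes (the 16-node fixture needs 2^15); beyond
the cap, `n_samples` uniform states are drawn from the seeded generator.

## Drugs and dose

A drug component targets a node or a single link, with dose `x` the
per-step suppression probability. Draws are independent Bernoulli across
steps, components, replicates and initial states, with no patterning, and
apply during both transient and steady phases. Doses 0 and 1 are
special-cased to consume no random draws, which makes the dose-0 run
bit-identical to the unperturbed one and dose-1 bit-identical to the
corresponding `I`-clamp — both are asserted as invariants. `death_ratio`
averages the death indicator over all initial states and `n_replicates`
schedules per state; the default is one schedule per state (the response is
defined as a ratio over initial states), and replicates exist purely for
variance reduction. Each sweep reseeds its generator from `config.seed`, so
identical profiles compared under identical perturbations share suppression
schedules exactly; this makes cancer ≡ control comparisons yield `f ≡ g`
rather than two noisy copies.

Combination curves (1-D) apply one shared dose to every component; the 2-D
landscape `f(x, y)` is the general object for independent dosing, with
optimality `f − g` cellwise.

IC50 has two modes. `scaled` (default) is the dimensionally consistent
interpolation `x1 + (0.5 − f(x1))/(f(x2) − f(x1)) · (x2 − x1)`; `literal`
evaluates `(0.5 − f(x1))/(f(x2) − f(x1)) + x1` exactly as that formula is
conventionally printed, omitting the grid-spacing factor (on the default 0.1
grid the two differ by the 10× stretch of the fractional term). Both return
1 when efficacy < 0.5. sMED/sMTD use the same first-crossing linear
interpolation at the 0.25 threshold; a control curve that never reaches it
yields sMTD = ∞ (window unbounded above), a cancer curve that never reaches
it yields sMED = NaN (window undefined).

## Categorization

Thresholds: efficacy 0.8, toxicity gap 0.5, potency gap 0.5, window 0.25,
death 0.9, all compared strictly. For the S test of a combination, each
component contributes its *single-target* curves (a node's own sweep plus
its outgoing links' sweeps; a link's own sweep plus its source node's
sweep), and a test passes if at least one component passes; the
combination's own joint curve drives the O test. O classification checks the
toxicity test first, then the potency test, else O3. Screening runs with the
damage input ON; drug-sensitivity validation utilities assume it OFF; the
control network uses the same input clamp as the cancer network it is
compared against. The triangle map enumerates all singles and pairs over the
designated target nodes, with NA cells exactly for same-source link pairs
and node-with-own-link pairs — a function of topology only.

Sensitivity classification directions (the binary sensitive/resistant calls
used when comparing simulated metrics with database values): lower is
sensitive for IC50-like quantities (simulated and experimental IC50, GR50,
GRmax), higher is sensitive for death-integral quantities (simulated AUC and
efficacy, GR_AOC), and experimental viability AUC is compared against the
cohort mean supplied by the caller. Non-finite values must be excluded
upstream and raise otherwise.

## Stratification

Each alteration subset of a profile (capped at 2^12 subsets) is simulated
and placed in the (efficacy, IC50) plane; neighbors of the original
network's point are subsets within Euclidean distance 0.1 (both axes already
live in [0, 1], so no rescaling is applied). The determinant is the
intersection of the neighbors' alteration sets, required to itself be a
neighbor; an empty or non-neighbor intersection means no determinant, and
such networks respond like the control. Where several incomparable minimal
neighbor sets exist they would each be reported ("minimal" is set-minimal,
not minimum-cardinality). Dominance is decided per desirable × undesirable
pair by simulating the union profile; levels follow the longest chain of
dominated determinants below each one (level 1 lowest). Cyclic pairwise
outcomes are detected and raised, never silently broken. The enrichment
baseline ranks single alterations by two-sided Fisher's exact association
with the D/U labels (scipy), each marker predicting its enriched class for
carriers.

## Synthetic fixtures and what green tests establish

No measured data ships with the package. Three designed fixtures plus two
random generators cover the test surface:

* **Toy network** (X → Z ← Y): Z copies X one step later, so under dose-`x`
  X-inhibition the death probability has the closed binomial form
  `P(Bin(steady_steps, x) ≤ ceil(steps·(1−θ))−1)` — the independent oracle
  for the Monte-Carlo engine.
* **16-node p53-like network**: a hand-built stand-in fixing only the
  structural facts that drive the screening combinatorics (16 nodes; target
  nodes AKT, BCL2, CYCE, MDM2, WIP1, ATM with 27 outgoing links, giving the
  480-perturbation screen). Its dynamics are designed, not transcribed: the
  control survives DNA damage because AKT sustains three redundant p53
  guards (MDM2, MDMX, BCL2); apoptosis (sustained BAX/CASP3) is
  self-maintaining once p53 latches PTEN → AKT-off; guard-disabling
  alterations (e.g. `BCL2_inact`) sensitize, guard-clamping alterations
  (`MDMX_act`, `BCL2_act`, `AKT_act`) confer dominant resistance.
  Quantitative claims tied to the reference model's exact parameters
  (cohort counts, screening census, specific sMTD orderings) can *not* be
  checked against this stand-in and the corresponding tests skip with that
  reason.
* **Dominance demo network** (10 nodes): a drug-target `guard` silencing a
  kill route, a `bypass` alteration that makes the drug effective in every
  initial state (desirable determinant), a `shield` alteration that vetoes
  the death readout outright (dominant undesirable determinant), and two
  reporter nodes with no path to the readout (verifiably neutral passenger
  sites). Ground-truth labels follow from the construction and are
  re-derived by simulation in the cohort generator.
* **Random networks**: an input→…→output backbone guaranteeing
  reachability, one feedback edge, density-driven extra links of either
  sign, and two sink reporters for passenger alterations. Alteration
  cohorts draw 1–4 alterations (uniform — a choice, since no canonical
  distribution exists for this) on distinct nodes, which guarantees
  conflict-free status profiles.
* **Causal implants**: `find_causal_plan` accepts a candidate alteration
  only if simulation shows its (efficacy, IC50) point at least 0.3 away
  from the control's — three times the determinant radius, so recovery is
  not decided by Monte-Carlo noise at the boundary.

A green suite therefore establishes that the machinery is correct on worlds
whose ground truth is known by construction — binomial closed forms,
designed attractors, implanted determinants. It does not establish
agreement with any measured cohort or with a reference model's parameter
values.

## Numerical choices and limitations

* All randomness flows from a single integer seed per config; results are
  bit-reproducible.
* The death-ratio engine is vectorized over initial states (one matrix
  multiply per step for the whole batch); a full 480-perturbation screen on
  the 16-node network enumerates 2^15 states per sweep and is minutes-scale,
  so the shipped screening example and pipeline default to sampled states
  and shorter windows; all defaults remain available.
* Status conflicts (one sample's alterations implying both `A` and `I` for
  a node) are a hard error by default; the random cohort generator avoids
  them by construction.
* Ternary Pearson similarity is undefined (NaN) against a constant profile,
  including the all-N control.
* Toxicity is modeled against a single alteration-free control network; no
  organ- or tissue-specific toxicity, no pharmacokinetics mapping dose to
  inhibition probability, and no multi-valued logic beyond the ternary
  clamps.
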