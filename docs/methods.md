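# Methods

## What the package models

`ctloop` is a desk-scale model of an autonomous formulation-development
platform for MNP-based nucleic-acid extraction. The physical platform is
abstracted into four pieces:

1. a mixed categorical/continuous **condition space** (ten categories, 43
   encoded features);
2. a **benchmark oracle**: a planted Ct response surface plus a measurement
   model (concentration term and replicate noise), standing in for robotic
   synthesis and qPCR scoring;
3. **initial-data generators** emulating proprietary industrial data and
   public literature data;
4. the **closed loop**: cross-validated surrogate selection, GA batch
   proposal, simulated measurement, append, stop/continue.

Everything downstream (trajectories, compactness, weighting factors,
consistency scores) is computed from these four pieces; no external data is
used anywhere.

## The response surface

`true_ct(s) = 26.0 + main effects + pairwise compatibility + decoy terms`,
all components ≥ 0 and zero at the planted optimum, so Ct 26.0 at
10⁵ copies/mL is the unique global minimum.

**Tuned categories.** Four categories carry the large main effects:
particle size (numeric, 200–1000 nm; quadratic penalty, 6 Ct at the range
edges, optimum 600 nm), functional group (0 / 2.4 / 4.0 Ct), molecular
crowding (0–3.8 Ct over five levels) and salting out (0–2.8 Ct). These are
the axes a campaign visibly tunes, and the axes that dominate the
importance profile.

**Platform categories and reagent families.** The six reagent-matching
categories (surfactant, chaotrope, binding alcohol, buffer, wash, elution)
each have five levels, index-aligned into five *reagent families* (family 0
is the gentle Triton/GITC/isopropanol chemistry). Any pair of platform
settings from different families costs 0.22 Ct; matched pairs cost nothing,
regardless of family. Because every level then has the same expected penalty
under uniform sampling, marginal statistics carry no information about which
chemistry is right — coherence must be learned jointly. The three design
consequences are deliberate:

- a fully coherent non-zero family incurs an additional all-or-nothing
  penalty of 1.0–1.15 Ct (a `CoherenceTerm`, active only when all six
  categories match that family). One step away from coherence the term
  vanishes but five mismatch penalties appear, so the decoy families are
  genuine local optima that single-category search cannot leave;
- the decoy cost is invisible to marginal *and* pairwise statistics and to
  measured selection along mixed-scheme paths (where the families are
  exactly symmetric), so which family a campaign aligns on is decided by
  its early data;
- platform categories keep tiny additive penalties (≤ 0.02 Ct, steps below
  the triplicate-mean noise floor of σ/√3 ≈ 0.038) purely so that
  variance-share calibration stays well-posed; they are too small for the
  loop to exploit.

The coherence penalty is an intentional generalization of pairwise
interactions: any decoy cost expressible pairwise creates gradients that a
measured, elitist batch loop exploits within a handful of rounds, which
erases the data-provenance effect the simulator exists to exhibit.

**Measurement.** A replicate at concentration q adds
`log2(10)·log10(q_ref/q)` (ideal doubling efficiency; q_ref = 10⁵ copies/mL)
and Gaussian noise: σ_auto = 0.065, σ_hitl = 0.40. σ_auto is set so that
five-replicate panels score `1 − sd ≥ 0.9` in ≈ 95 % of panels (10th
percentile score ≈ 0.91); a tempting round value of 0.08 fails that
reproducibility contract, because the sd of five replicates has substantial
sampling spread (P(sd ≤ 0.1 | σ = 0.08) ≈ 0.82). σ_hitl puts the median
manual panel score near 0.62, inside the 0.5–0.7 band. Both are
configurable.

## Initial-data generators

**Industrial** (`gen_industrial`, default n = 192, i.e. four 48-batches):
a compact cloud around an anchor inside the "manufacturable" region. The
anchor is pinned to the optimal platform chemistry (the joint reagent
matching a manufacturer has already worked out) and varies only the four
tuned categories; cloud members flip each categorical with probability 0.10
and jitter numerics by 0.10 of the range. The anchor is placed by a
calibration search so the cloud's best (lowest) label lands at 35.5 ± 0.5 Ct:
candidates are drawn from a pool, the cloud is generated and labeled, and
the anchor target is shifted by the observed miss (bounded retries,
deterministic per seed). Labels are triplicate means under the automated
noise regime.

**Literature** (`gen_literature`, default n = 192): schemes uniform over the
whole space; each record is attributed to the nearest of n/16 uniformly
placed synthetic "lab centers", and all of a lab's labels share an additive
N(0, 1.0 Ct) offset on top of measurement noise. Assigning labs by region
rather than at random makes the offsets spatially structured — protocol- and
instrument-level heterogeneity that misleads a model about the shape of the
surface, not just iid noise.

What this generator pair reproduces is the qualitative contrast: the
industrial cloud is compact (PCA compactness ≈ 1.3 vs ≈ 2.6 for literature)
and, although its labels start no better (best ≈ 35.5 vs ≈ 28–30 for the
best-of-192 uniform draw), campaigns seeded with it reliably reach the
Ct ≤ 26.5 requirement in ~3 rounds, while literature-seeded campaigns
usually lock into a coherent but inferior reagent family and stall ~0.5–1 Ct
short of the requirement through round 9. What it does *not* model: real
literature corpora are biased toward publishable (good) results, report
heterogeneous protocols and concentrations rather than a shared condition
space, and are far sparser than 192 rows; the generators make none of these
claims.

## Surrogate registry and selection

Ten regressors: random forest (100 trees), extra trees, histogram gradient
boosting, k-NN (k = 5), RBF kernel ridge, `quad_ridge` (ridge on [X, X²]:
additive level effects plus smooth quadratic numeric response), ridge,
lasso, and a constant baseline; a shallow-MLP factory is available but not
registered by default (it is the one family that is slow and
convergence-fragile at a few hundred samples per round, without adding a
distinct inductive bias to the set). Selection is by mean 5-fold CV R²
(shuffled, seeded), ties broken by CV MSE then registry order; the winner is
refit on all data. Train/CV MSE histories feed an overfitting monitor that
flags a train/CV ratio < 0.25 in two consecutive rounds.

The `quad_ridge` entry matters for importance analysis: tree ensembles
systematically under-represent smooth numeric curvature relative to
categorical steps when probed under the uniform measure, which distorts
recovered weights. On an additive surface the quadratic ridge is the exact
function class, wins the CV selection on merit, and extrapolates gracefully;
on the non-additive default surface the tree models remain available and the
selection decides per round.

## Weighting factors

Per-category importance is the block-permutation sensitivity of the fitted
surrogate on a uniform probe (default 2,000 schemes): each category's
feature block is jointly permuted across probe rows and the mean squared
shift of the surrogate's predictions is recorded, then normalized to sum
to 1. For an additive surface this equals `2·Var` of the category's
contribution under the uniform measure, so normalized sensitivities recover
planted variance shares. The block (not per-column) permutation is
deliberate: one-hot indicator columns are redundant, and permuting them
independently splits a category's effect across columns unpredictably.

`calibrate_variance_shares` rescales each category's penalties by
`√(target/current)` (total variance preserved, optimum location unchanged,
interaction and coherence terms zeroed so the calibrated surface is exactly
additive) and verifies the achieved shares by Monte Carlo to ±0.02. The
reference profile concentrates 0.357 / 0.264 / 0.151 / 0.125 on particle
size, functional group, molecular crowding and salting out; the remaining
0.103 is spread over the six platform categories roughly in proportion to
their roles (0.010–0.030 each).

The recovery experiment runs the industrial-start campaign to the
efficiency-grade target (Ct 26.0, up to 9 rounds), trains on all accumulated
records and reads the weights from the uniform probe; medians over 5 seeds
land within ~0.02 of the planted profile.

## Batch proposal

The GA works on schemes directly: tournament selection (size 3), uniform
per-category crossover (rate 0.9), per-category mutation (level resampling /
clipped Gaussian jitter at 0.1 of a numeric range; rate 0.15), elitism 8,
population 256, 60 generations. Every scheme scored during a run is
archived, and the batch is the fitness-sorted archive filtered for validity,
novelty (no re-proposing evaluated schemes) and pairwise categorical
diversity (Hamming ≥ 1). Fitness is |predicted − target| ("closest") or the
raw prediction ("minimize"). On all-categorical spaces small enough to
enumerate, generation zero is seeded with the full enumeration, so with
diversity and dedup disabled the batch provably equals the exhaustive
top-k — the property the test suite checks against brute force.

In campaign mode the 48 slots are sub-grouped: 12 *probes* vary one category
at a time around the incumbent best measured scheme (categories ordered by
the current surrogate's weighting factors; numeric categories get a local +
coarse value grid), 8 *epsilon* slots hold uniformly random unseen schemes
(keeping the store informative across the space, for the overfitting monitor
and post-campaign importance analysis), and the remainder exploit the GA
ranking. Without the probe slice, campaigns seeded from compact data stall:
the surrogate never revisits levels absent from its cloud, and the GA
faithfully avoids what the surrogate (wrongly) scores badly.

A deterministic *advisor* (`rule_advisor`) stands in for external
suggestion sources: it recombines the per-category best marginal levels of
the top 10 % lowest-Ct records and injects the suggestions into generation
zero. It is a pluggable callable; anything with the same signature can
replace it.

## The loop

Requirement intake first checks the store (`lookup_meeting_requirement`);
an existing qualifying record ends the campaign at zero rounds. Otherwise
each round trains/selects on all data, proposes a batch, measures each
proposal as the mean of 3 replicates at the requirement concentration under
the automated regime, appends records (append-only store, 1-based rounds;
initial data is round −1), and stops when the best *measured* mean Ct
reaches the target (the loop observes noisy measurements, never the oracle's
truth) or the round budget is exhausted. A single campaign seed derives an
independent sub-seed per (round, stream) via `SeedSequence`, so a saved
campaign resumes bit-identically. State round-trips through versioned JSON.

## Numerical choices and degenerate inputs

- Encoding: one-hot per categorical level, min–max scaling per numeric;
  decode validates one-hot blocks sum to exactly 1.
- Consistency score uses the sample (n−1) standard deviation — conservative
  for 3–5 replicates — and returns exactly 1.0 for identical replicates.
- Dataset CSVs write floats with shortest round-trip `repr` and read them
  with round-trip parsing, so write→read is lossless.
- PCA projections fix component signs (largest-|loading| positive);
  compactness is measured in the full encoded space because 2-D compactness
  depends on the projection.
- Scheme equality and deduplication are exact on assignments; GA
  tie-breaking among equal-fitness schemes is lexicographic on the encoded
  vector, for determinism.
- Zero-variance labels, empty registries, empty concentration lists,
  sub-minimum probe sizes and exhausted spaces raise immediately with named
  causes.

## Problem sizes

The default study conditions are sized to a workstation: initial datasets of
192 records (four 48-batches), 48-scheme rounds, up to 9 or 15 rounds, 2,000
probe schemes, 20,000 Monte-Carlo samples for share calibration, 1,000
panels for consistency statistics, medians over 5 seeds (20 for generator
calibration, 10 seed pairs for the provenance comparison). A full campaign
runs in ~10–25 s on one CPU; the complete reproduction script in
`scripts/acceptance.py` takes about a minute.

## Known limitations

- The oracle is a benchmark surface, not a mechanistic model of binding or
  lysis chemistry; its family/decoy structure is a minimal construction that
  makes data provenance matter, not a claim about real reagent
  incompatibilities.
- The Ct↔efficiency conversion assumes ideal doubling (base 2,
  configurable); real assays have amplification efficiencies below 1 and
  matrix effects.
- Weighting-factor recovery depends on the selected surrogate generalizing
  under the uniform measure; with strongly non-additive surfaces and purely
  exploitative sampling the recovered weights reflect the model's
  extrapolation as much as the surface.
- Literature heterogeneity is reduced to spatially structured additive lab
  offsets; publication bias, protocol mismatch and missingness are out of
  scope.
- The advisor is a deterministic heuristic; it demonstrates the
  suggestion-injection mechanism, not the capabilities of any particular
  external recommender.
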