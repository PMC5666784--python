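# Methods

## Data model and redundancy treatments

A screen is an ordered list of `(state_id, parent_id, score)` rows, one per
enumerated ligand state, plus direction metadata (`lower_better` for
docking-like scores, `higher_better` for similarity-like scores). Scores
are normalized to an internal higher-is-better scale once at ingestion;
every metric consumes the normalized order. Sorting is stable, so entries
with tied scores keep their input order and tie blocks are contiguous and
reproducible.

Labels come from an activity table of residual kinase activities (percent
of uninhibited enzyme activity remaining per compound and kinase). A
compound is active when its primary-kinase residual is **at or below** the
threshold (default 40%); the boundary is inclusive and the threshold is
configurable. Every state inherits its parent's label.

The **redundant** treatment evaluates the full state population; **no
duplicates** keeps each parent's best-scoring state (within-parent ties:
the earlier input row). Collapse is idempotent and cannot demote a parent
past another parent it beat. Actives a screen failed to report are, by
default, appended below every reported entry with a warning — an
unreported active is a screened-last active for recovery arithmetic — and
this can be switched to a hard error.

Two rank conventions are used deliberately:

* **worst-in-tie-block** ranks for screening percentage and fold
  enrichment — physically you cannot stop screening in the middle of a tie
  block, so ties are counted pessimistically;
* **average** ranks for the AUC — the Mann–Whitney form with ties at half
  credit, which equals the trapezoidal area under the ROC polygon with tie
  blocks drawn as diagonal segments;
* the exponential metrics (RIE/BEDROC) use the 1-based position in the
  stable order. Their literature formalism assumes distinct scores and
  fixes no tie convention; the stable position is deterministic and
  reproducible, and with continuous scores the three conventions coincide.

## Metrics

RIE is `Σ_i exp(−α x_i)` divided by its exact expectation under uniform
random placement, `(n/N)(1−e^{−α})/(e^{α/N}−1)` — the denominator is the
exhaustive mean over all single-active placements, so averaging RIE over
all N positions of one active gives exactly 1.

**BEDROC is computed as the exact min–max rescaling of RIE** between its
brute-force extremes (actives at ranks `1..n` vs `N−n+1..N`, closed
geometric sums). The commonly quoted closed form
`RIE·R_a·sinh(α/2)/(cosh(α/2)−cosh(α/2−αR_a)) + 1/(1−e^{α(1−R_a)})` is the
large-N approximation of this rescaling; at N = 10 it misses the endpoints
by ~5·10⁻⁵, whereas the exact form guarantees perfect → 1 and inverted → 0
to machine precision and is linear in RIE (hence monotone under
active-promoting swaps). A conditioning warning is emitted when
`α·(n/N) > 1`, where the exponential weight saturates within the
active-sized head of the list and early-recognition contrast is lost.

Total gain standardizes the mean absolute deviation of the predictiveness
curve from the prevalence. The curve is estimated per score-tie block: the
proportion of actives in the union of the block with a centered
`tg_window`-entry span, truncated at the list ends. With distinct scores
this is a plain centered moving window; a block wider than the window
contributes its own label proportion, because rank order inside a tie
block is arbitrary and the estimate must not depend on it. Consequences:
a fully tied list gives exactly 0, and complete class separation with
within-class ties gives exactly 1; with distinct scores the separated
value approaches 1 from below as the window shrinks relative to N (the
residual is boundary smoothing of order `window / (2π(1−π)N)`). The window
defaults to `max(20, N // 25)` — small enough to resolve an active-rich
head, large enough that the null fluctuation `≈ sqrt(π(1−π)/w)` keeps TG
well below 0.1 on uninformative scores at N ≈ 2000. The estimator name is
recorded in every report. TG is clipped to [0, 1].

Fold enrichment at recovery fraction `f` over `m` tracked actives is
`f / s`, where `s` is the screened fraction (worst-tie rank / N) at which
the `⌈f·m⌉`-th of them appears; uniform random placement gives 1 in
expectation. Percentages in display CSVs are rounded to two decimals; JSON
reports keep full double precision.

An `active_subset` switch restricts the active definition to an explicit
compound list (or, in the CLI, to the potent subset at residual ≤ 25%),
because benchmark reports sometimes track all threshold actives and
sometimes only the potent hits; both readings are supported for every
metric.

One documented oddity of paired redundant/no-duplicates reporting: RIE can
shift in the opposite direction to AUC and BEDROC between treatments. This
is arithmetically possible because both N and n change when states
collapse — RIE's random-placement normalization rescales with `(n, N)`,
while BEDROC's additional min–max anchoring absorbs most of that
rescaling. The comparison report therefore always carries both treatments'
`(n, N)` alongside the deltas.

## Synthetic campaign generator

The generator emulates the statistical structure the evaluation assumes,
not chemistry: no structures, no physics, no docking. Defaults describe
the reference campaign the package is designed around: `n_parents = 1364`,
`n_active = 19`, `n_potent = 4`.

* **Activity table.** Class census is exact by construction: potent
  actives draw primary-kinase residuals uniformly in [5, 25] (bracketing
  the strongest confirmed hits), remaining actives in (25, 40], inactives
  in (40, 100]; off-target kinase residuals are uninformative draws. The
  printed residuals of real hit panels are too few to support a
  distributional claim, so uniform-within-bracket is used as the
  assumption-minimal choice.
* **Molecular size and enumeration.** Each parent carries a latent
  lognormal size (log-mean 0, log-sd 0.6), independent of activity class.
  State counts are `1 + Poisson(λ0 · size^γ)` with `λ0 = 4`, `γ = 2.5`:
  median ≈ 5 states per parent, upper tail into the hundreds — the
  qualitative shape of real enumeration, where expansion ranges from a few
  fold to orders of magnitude for conformer-pregenerating workflows.
* **Scores.** On the internal scale, parent means are `N(Δ, 1)` for
  actives and `N(0, 1)` for inactives with `Δ = 1.5` (a realistic
  mid-0.8s dedup AUC regime); states add independent `N(0, σ_state)`
  noise, `σ_state = 0.05`. The within-parent spread is kept small relative
  to the between-parent spread because best-state selection turns state
  noise into a small treatment-dependent bias (a max-statistic effect of
  order `σ_state²`): the generator's uncoupled regime is *designed* to be
  a null for the redundancy comparison, and a small `σ_state` keeps that
  null clean while still exercising the collapse machinery.
* **The bulk artifact.** With coupling strength `rho_bulk ∈ [0, 1]`
  (default 0.5), inactive parents receive a score penalty
  `rho_bulk · 2.0 · z` (inactive-SD units, `z` = standardized log size).
  Large inactives then have simultaneously poor scores and many states:
  their states flood the bottom of the redundant list and inflate every
  enrichment metric relative to no-duplicates. At `rho_bulk = 0`
  multiplicity is independent of score and the inflation vanishes; the
  Monte-Carlo census in the test suite (200 seeds per arm at the default
  collection size) checks both regimes.

All randomness flows from one user-facing seed through deterministic
per-stage child streams (collection, enumeration, scores), so reruns are
byte-identical and re-running a later stage does not perturb an earlier
one. Every output file carries a provenance block (config echo, seed,
package version, input hashes where applicable).

## Comparisons

* `compare_redundancy` pairs the two treatments of one screen metric-wise
  and reports the AUC delta as a percent of the 0.5 random-to-ideal
  range (the maximal reasonable AUC variation), keeping cross-study
  statements about redundancy impact on a common scale.
* `template_sensitivity` summarizes a panel of screens of one collection
  by per-metric mean/min/max/range and flags the min/max-AUC templates;
  reports must share the treatment and (when recorded) the tracked active
  set — the active *entry* count may differ between redundant screens
  because state expansion is screen-specific.
* `evaluate_transfer` rank-correlates stage-1 and stage-2 AUCs over shared
  templates (Spearman, ≥ 3 shared templates) and flags whether the
  best-AUC template coincides — the operative question when a fast
  ligand-based stage picks the single template for a slow docking stage.
  It consumes reports, not raw screens: the logic is independent of how
  the second stage's rank lists were produced.

## What the synthetic tests do and do not show

Passing the suite demonstrates that the metric arithmetic is exact against
independent oracles, that the redundancy-inflation mechanism behaves as
designed under its stated statistical model, and that the pipeline is
deterministic end to end. It does not validate the generator as a model of
any particular chemical library: real score distributions are non-Gaussian
and multimodal, enumeration depends on ionizable/stereogenic chemistry
rather than a single latent size, state scores of one parent are strongly
correlated in structured ways, and real active sets are tiny and
structurally clustered. Conclusions about a real screen must come from
evaluating its actual rank lists through the same interfaces.

## Problem sizes

The test suite runs the Monte-Carlo arms at the full default collection
size (1,364 parents, ≈ 18k enumerated states per run, 200 seeds per arm)
and completes in well under a minute in total; unit fixtures use
collections of 120–200 parents, which exercise every code path at
negligible cost.
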