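# screenrich

Redundancy-aware enrichment evaluation for virtual screens.

## The problem

Retrospective benchmarking of virtual screening asks how well an in-silico
method — docking against a protein structure, or 3D shape/pharmacophore
similarity to a known active query — ranks the experimentally confirmed
actives of a fully assayed compound collection ahead of everything else.
A typical setting: a 1,364-compound diversity set screened in vitro against
a kinase, with 19 compounds at or below the 40% residual-activity threshold
(4 of them potent) — a 0.29% hit rate for the potent subset.

One subtlety dominates this kind of evaluation. Before 3D screening, every
2D compound entry is *enumerated* into its plausible protonation states,
tautomers and stereoisomers, unevenly inflating the library (a few states
for most molecules, hundreds for some). Enrichment can then be computed
over the whole state population (**redundant** treatment) or after keeping
only each compound's single best-scoring state (**no duplicates**).
Because the molecules that are too large to bind are often exactly the
molecules with the most enumerable states, their states pile up at the
bottom of the redundant list and *artificially inflate every enrichment
metric*. `screenrich` makes both treatments explicit, quantifies their gap,
and ships a generator that reproduces the inflation mechanism so the whole
pipeline is testable without commercial screening software.

## The metric panel

For a ranking of `N` entries containing `n` actives at ranks `r_i`
(relative ranks `x_i = r_i / N`, prevalence `π = n/N`):

- **ROC AUC** — `P(score_active > score_inactive)`, ties ½; 0.5 = random,
  1.0 = ideal. AUC deltas are also reported as a percent of the 0.5
  random-to-ideal dynamic range.
- **RIE** — `Σ_i exp(−α·x_i) / [ (n/N)(1−e^(−α)) / (e^(α/N)−1) ]`:
  exponentially rank-weighted recovery normalized so that random placement
  gives 1 in expectation. `α` (default 20) sets the early-recognition
  horizon (top ~1/α of the list).
- **BEDROC** — RIE rescaled to [0, 1] between its exact minimum (actives
  last) and maximum (actives first).
- **Total gain (TG)** — standardized mean absolute deviation of the
  predictiveness curve (local probability of activity along the rank axis,
  estimated by a tie-aware centered moving window) from the prevalence:
  `TG = mean|R̂ − π| / (2π(1−π))`; 0 = uninformative scores, 1 = complete
  separation.
- **Screening percentage** — `100·rank/N` per active with pessimistic
  (worst-in-tie-block) ranks: the fraction of the list you must physically
  screen to reach it.
- **Fold enrichment** — recovery fraction ÷ screened fraction at which it
  is achieved (e.g. 50% of actives recovered after screening 1.76% of the
  list → 28-fold over random).
- **Hit rate** — `100·hits/screened`.

## Worked example

Generate a synthetic campaign (collection, activity table, a docking-like
and a similarity-like screen) and evaluate the docking-like screen under
both redundancy treatments:

```
$ screenrich simulate --out demo --seed 7
$ screenrich evaluate --screen demo/structure_based.csv \
    --activity demo/activity.csv --treatment both --out demo/eval
structure_based [redundant]: AUC=0.972 RIE=11.226 BEDROC=0.634 TG=0.888 (N=18254, n=228)
structure_based [no_duplicates]: AUC=0.855 RIE=4.761 BEDROC=0.273 TG=0.655 (N=1364, n=19)
```

The redundant list has 18,254 entries because the 1,364 parents expanded
unevenly into enumerated states (the 19 active parents contribute 228
state rows); collapsing to best states restores one row per parent. The
redundant AUC reads 0.117 higher — `demo/eval/redundancy_comparison.json`
reports that as 23.4% of the 0.5 random-to-ideal range, which is inflation
by the bulk artifact, not better screening. The no-duplicates report also
carries per-active screening percentages and fold enrichments (here
5.5-fold at 50% recovery, hit rate 1.39%).

Screens are plain CSVs (`state_id,parent_id,score`) with a JSON sidecar for
direction/template metadata, so real rank lists exported from docking or
similarity software can be evaluated the same way. `screenrich compare`
summarizes template sensitivity across a panel of report JSONs, and
`screenrich combine` checks whether stage-1 (ligand-based) template
performance predicts stage-2 (structure-based) performance via a Spearman
rank correlation. Everything is also available as a library
(`import screenrich`).

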