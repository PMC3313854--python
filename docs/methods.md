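# Methods

## Problem and data model

The package assesses short-term motor-state change in Parkinson's disease
from pairs of UPDRS examinations.  Thirteen motor items (falling 13,
freezing of gait 14, rest tremor 20, action tremor 21, finger taps 23,
hand movements 24, rapid alternating movements 25, leg agility 26, posture
28, gait 29, body bradykinesia 31, dyskinesia duration 32, off-time 39)
are scored 0–4.  Because parkinsonism is asymmetric, limb items are scored
per side — item 20 per limb (RH/LH/RF/LF), hand items 21/23/24/25 left and
right, leg item 26 left and right — expanding 13 items into 21 attributes
(`d13`, …, `d23RH`, …).  The schema is configuration (YAML), so a different
lateral expansion is a one-line change.

The training unit is a *delta record*: per-attribute `current − historical`
change in UPDRS points, in [−4, 4], optionally tagged with an expert
decision in {0 stable, 1 warning, 2 alarm}.  Expert panels label exam
pairs independently; every (pair, expert) vote becomes its own table row —
votes are never majority-aggregated, so rater conflict survives as table
inconsistency, which is exactly what the rough-set machinery consumes.
Negative deltas (improvement) are kept; experts are simply never expected
to grade improvement as deterioration, and the synthetic ground truth maps
pure-improvement records to class 0.

**Deduplication** removes repeated entries per rater: two rows are
duplicates when the *same expert* produced the same delta vector with the
same decision (which happens when two patient-pairs show identical score
changes).  Agreement between different experts on the same pair is
evidence, not redundancy, and is kept.  A stricter table-wide scope
(collapse identical (deltas, decision) rows across raters) is available as
`deduplicate(table, scope="table")`.  Contradictory rows are never merged
under either scope.  With this semantics the bundled 74-pair × 4-expert
fixture holds 296 rows and deduplicates to exactly 284 (three cloned
delta vectors × 4 experts = 12 repeated entries).

## Rough-set layer

Implemented literally from the definitions over discrete delta symbols:
indiscernibility partitions, lower/upper approximations, boundary,
positive region and γ, and the decision-relative discernibility matrix
(entries only for decision-differing pairs; an empty entry marks a
contradictory pair and is skipped by reduct search but surfaced in the
inconsistency report).  Reducts come in two forms:

- `find_reducts`: exhaustive enumeration by subset size, refused above 15
  attributes (the bound is configurable); returns *all* reducts.
- `greedy_reduct`: Johnson's heuristic — repeatedly take the attribute
  covering the most uncovered nonempty matrix entries (ties broken
  lexicographically by attribute name) — followed by a γ-preserving
  pruning pass, so the result is a genuine reduct (minimal under single
  removal).

`core` is the intersection of all reducts (computed exactly below the
exhaustive bound, via singleton matrix entries above it).  Nothing
downstream depends on it; it is provided for completeness.

## Discretization

Rules use strict-inequality interval conditions on integer deltas, so
induction first places half-integer cuts (`v + 0.5` between consecutive
observed values).  Cut selection is a two-pool greedy set cover of the
decision-differing record pairs:

1. **Candidate filter.**  Each attribute is discretized independently with
   the Fayyad–Irani recursive entropy/MDL criterion; only thresholds with a
   real marginal association to the decision enter the preferred pool.
   This matters: an unfiltered maximum-pair-coverage greedy will happily
   substitute a cut on an irrelevant, high-variance attribute (which
   straddles ≈ 2p(1−p) of *all* remaining pairs) for a genuinely
   class-determining magnitude boundary, and the induced rules then fail to
   transfer beyond the training sample.
2. **MD greedy.**  Retain the preferred candidate discerning the most
   still-undiscerned pairs (ties: attribute name, then threshold).  When
   the preferred pool is exhausted but discernible pairs remain — typical
   of noisy, inconsistent tables, where contradictory labels sit on
   otherwise irrelevant attributes — the greedy continues over the full
   candidate pool, so every pair the raw integers discern is discerned and
   the discretized positive region equals the exact one.
3. **Redundancy elimination.**  Cuts are dropped newest-first while full
   discernment is preserved.

## Rule induction

**RS.**  Per decision class, LEM2-style sequential covering of the class's
lower approximation in the discretized space: grow a conjunction of
elementary interval conditions — preferring the condition covering the most
still-uncovered concept records, ties broken by fewest covered
non-concept records, then lexicographically — until everything covered lies
inside the concept; drop redundant conditions (growth order); remove the
covered records; repeat.  Rules made redundant by the rest of the set are
discarded.  Because covered records always lie in the lower approximation,
every RS rule has confidence 1 on the inducing table, and every record in
the positive region is matched by a rule of its own class.  A table whose
records all share one class yields a single unconditional rule (rendered
`Iftrue=>…`); a class with an empty lower approximation yields no rules and
a logged warning.

**RS-g.**  The variable-precision generalization: the covering target is
the β-lower approximation (elementary sets with class purity ≥ β,
β ∈ (0.5, 1], default 0.8 — the midpoint of the usual variable-precision
operating range), and each induced rule is then shortened greedily,
dropping at every step the condition whose removal leaves the highest
table confidence, as long as that confidence stays ≥ β.  Duplicate rules
produced by shortening are collapsed.  Support and confidence are always
recomputed on the full table after every transformation.

Purity and confidence comparisons use a 1e-12 absolute slack so that exact
rational values (e.g. 4/5 vs β = 0.8) are not lost to floating-point
rounding.

## Classification and evaluation

All matching rules are collected.  One matching class → that class.
Several → support×confidence-weighted vote.  No match → partial matching:
rules with the highest fraction of satisfied conditions vote.  Any
remaining tie resolves to the most severe class — the system's purpose is
alerting, and a missed alarm is the costly error.  A 1-NN Manhattan
baseline (`nn_baseline`) is included as a sanity check, with
lower-index/severity tie-breaks.

Evaluation reports a 3×3 confusion matrix and three efficiencies (1
decimal): case 1 = trace/total; case 2 collapses {0,1} vs {2}; case 3
collapses {0} vs {1,2}.  Collapsing only moves error cells onto the
diagonal, so case 2, case 3 ≥ case 1 for every matrix.  The train/test
split is stratified (largest-remainder allocation, per-class proportions
within one record), seeded, and sends singleton classes to training with a
warning.

## Synthetic cohort

The generator emulates the study conditions the package is built for: 74
historical/current exam pairs, each labeled by a panel of 4 experts,
examinations ~8 months apart (uniform 150–340 days).  Baseline scores are
i.i.d. categorical over 0–4 (probabilities 0.25/0.30/0.25/0.15/0.05, a
moderate-stage cohort); per-attribute increments are drawn independently —
hence asymmetric sides — from {−1,0,1,2,3} with probabilities
0.06/0.64/0.20/0.08/0.02 (mostly unchanged, worsening-biased, occasional
one-point improvement), and current scores are clipped to 0–4.

The default ground-truth labeler scores
`s = Σ_a w_a · max(Δ_a, 0)` with weights 2.0 on the high-risk axial
symptoms — falling (d13), freezing (d14), gait (d29) — and 0 elsewhere,
thresholds 2 (warning) and 4 (alarm).  Clinically: one point of worsening
on a key axial symptom → warning; a two-point jump or two worsening key
symptoms → alarm; pure improvement → stable.  Two properties motivated
this default: (a) experts are said to weight symptom importance rather
than sum raw points, and (b) with these weights every class region is a
union of per-attribute intervals, so an interval-rule learner *can*
represent the labeler exactly — making "the pipeline recovers the
generating process from noise-free data" a well-posed test.  Weights and
thresholds are configuration, not claims about true clinical weighting;
an explicit rule set can be substituted as ground truth.

Expert noise is ordinal-adjacent: with probability `expert_noise` a rater
reports a neighboring grade (0↔1, 2↔1, 1→0 or 2 equiprobably), never
stable↔alarm directly — split votes in practice are between adjacent
severities.  The bookkeeping fixture (`make_panel_fixture`) plants
exactly three cloned delta vectors among 74 otherwise-distinct pairs and
labels them noise-free, producing 296 rows → 284 after per-rater
deduplication, deterministically per seed.

**What the generator does not model:** real UPDRS item correlations
(items are drawn independently), medication on/off fluctuations,
longitudinal trajectories beyond a single pair, rater-specific bias
(noise is i.i.d. across experts), and any deterioration signal on the 18
unweighted attributes.  Passing tests therefore demonstrate algorithmic
correctness and the qualitative noise/generalization behavior, not
clinical performance.

## Problem sizes

The bundled experiments run at the cohort scale the package targets:
284–296-record tables, 21 attributes, 1,000-record recovery samples, 20
noisy replicates, 200 oracle-comparison tables of ≤ 8 attributes × ≤ 40
records.  The full test suite and the acceptance script each complete in
well under a minute on one CPU.

## Known limitations

- Exhaustive reduct search is exponential and deliberately bounded; the
  21-attribute space uses the greedy reduct.
- Rule counts depend on the covering order and cut set; they are reported
  but not meaningful as exact reproducible quantities.
- The β-purity criterion evaluates elementary sets of the *training*
  table; very small blocks (size < 1/(1−β)) can only be pure or excluded.
- Partial matching is a heuristic fallback; records far from every rule
  are still forced into a class (by design — the system must always answer
  — but the `resolution` field marks such answers as lower-trust).
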