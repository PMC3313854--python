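# pdalert

Rule-based decision support for monitoring motor-state deterioration in
Parkinson's disease (PD).

PD progression is tracked with periodic clinician-scored UPDRS (Unified
Parkinson's Disease Rating Scale) examinations: each motor item is rated
0–4.  Given a *historical* and a *current* examination of the same patient,
the clinically relevant question is whether the change warrants an alert.
`pdalert` learns that judgment from panels of experts who label pairs of
examinations on a three-step scale — `0` stable, `1` slight deterioration
(*warning*, low-priority alert), `2` severe deterioration (*alarm*,
high-priority alert) — and turns the labeled change vectors into
human-readable decision rules such as

```
IfΔUPDRS13<1&-1<ΔUPDRS14<2&ΔUPDRS23RH<1&ΔUPDRS29<1=>output=1-'warning'
```

i.e. a conjunction of strict-inequality interval conditions on per-item
UPDRS changes (Δ), which a neurologist can read directly.

## The model

Expert labels conflict: different raters grade the same change differently.
`pdalert` therefore uses **rough sets**, which handle inconsistent decision
tables natively.  For a table `U` of labeled change vectors and an
attribute subset `B`:

- the *indiscernibility relation* partitions `U` into elementary sets of
  records agreeing on `B`;
- a class `X` is approximated from below (`B̲X`: elementary sets wholly in
  `X`) and above (`B̄X`: elementary sets meeting `X`);
- the *positive region* `POS_B = ∪_X B̲X` and the dependency
  `γ_B = |POS_B| / |U|` quantify label consistency (`γ = 1` iff the table
  is conflict-free);
- *reducts* are minimal attribute subsets preserving `POS`, computed
  exhaustively or with Johnson's greedy heuristic on the discernibility
  matrix.

Rules are induced by LEM2-style sequential covering of each class's lower
approximation in a discretized (interval-cut) space, so **RS** rules are
certain (confidence 1 on the training table).  The generalized variant
**RS-g** uses the variable-precision model: it covers the β-lower
approximation (elementary sets with ≥ β class purity, default β = 0.8) and
then shortens each rule while its training confidence stays ≥ β.  Shorter,
slightly impure rules trade training coverage for better behavior on unseen
patients.  Classification resolves conflicts by support×confidence-weighted
voting, falls back to partial (closest-rule) matching, and breaks remaining
ties toward the more severe class, so borderline cases raise rather than
silence alerts.

Evaluation uses a 3×3 confusion matrix and three *efficiency cases*:
case 1 is 3-class accuracy; case 2 merges {stable, warning} vs {alarm}
(recognition of a high-priority alarm); case 3 merges {warning, alarm} vs
{stable} (recognition of any alert).

No clinical dataset ships with the package; a synthetic cohort generator
(`pdalert.simulate`) produces exam pairs with asymmetric per-side
progression, a configurable ground-truth severity labeler, and panels of
noisy experts with ordinal disagreement.  See `docs/methods.md` for the
full model description and its limitations.

## Worked example

```
$ pdalert simulate --panel-fixture --seed 1 --out table.csv
wrote 284 records to table.csv
$ pdalert split --table table.csv --train-out train.csv --test-out test.csv
split 284 -> 142 train + 142 test
$ pdalert induce --table train.csv --mode RS --out rs.json --text-out rs.txt
RS--10 rules -> rs.json
$ pdalert evaluate --rules rs.json --table test.csv --out eval.json
n=142 case1=100.0% case2=100.0% case3=100.0%
```

`simulate --panel-fixture` generates the bookkeeping cohort — 74 exam pairs,
each labeled by 4 noise-free experts (296 votes), deduplicating to 284
records — and the stratified split halves it into 142 + 142.  Because the
noise-free labels are a deterministic function of the change vector, the
induced certain rules classify the held-out half perfectly; the three
efficiencies are all 100%.  The rule report (`rs.txt`) begins:

```
Rule base:
  IfΔUPDRS14<1&ΔUPDRS29<1&ΔUPDRS13<1=>output=0-'stable'  [support=60, confidence=1.000]
  IfΔUPDRS14<1&0<ΔUPDRS29<2&ΔUPDRS13<1=>output=1-'warning'  [support=17, confidence=1.000]
  ...
```

With rater noise the picture changes to the realistic one:

```
$ pdalert simulate --seed 3 --pairs 74 --noise 0.15 --out noisy.csv
wrote 296 records to noisy.csv
$ pdalert induce --table noisy.csv --mode RS   --out nrs.json
RS--23 rules -> nrs.json
$ pdalert induce --table noisy.csv --mode RS-g --out nrsg.json
RS-g--22 rules -> nrsg.json
$ pdalert evaluate --rules nrs.json  --table noisy.csv --out ev1.json
n=296 case1=81.1% case2=92.9% case3=85.1%
$ pdalert evaluate --rules nrsg.json --table noisy.csv --out ev2.json
n=296 case1=82.1% case2=90.2% case3=91.2%
```

Conflicting votes put part of the table outside the positive region, so
even training accuracy stays below 100%; note that the collapsed cases 2
and 3 always sit at or above case 1.

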