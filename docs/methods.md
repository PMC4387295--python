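# Methods

## The estimation problem

Given many noisy pairwise judgments "ADR *i* is more severe than ADR *j*",
estimate a single global severity order (and a score per term).  Pairwise
comparison is used because absolute severity scales are hard for non-experts
to apply consistently, while binary choices are fast and well suited to
microtask crowdsourcing.  Only a small fraction of all C(N, 2) pairs is ever
judged, judgments conflict, and some respondents are spammers, so the pipeline
has three statistical jobs: detect unreliable workers, aggregate conflicting
votes, and turn a sparse partial tournament into a total order.

## Worker model (synthetic studies)

Simulated workers follow a Bradley–Terry-style logistic choice rule: a
diligent worker presented with terms whose true severities differ by
`gap = |s_i − s_j|` picks the truly more severe one with probability
`logistic(beta * gap)`.  `beta` is the discrimination of the crowd
(default 6, giving ≈ 88% accuracy at a gap of one third of the scale —
a realistic level for lay judgments of medical terms); `beta → ∞` gives
deterministic workers, `beta = 0` coin flips.  A fraction of workers
(`spammer_fraction`, default 0.1) ignore content entirely and answer
uniformly.  Spammers also answer gold questions at random, which makes the
filter's power analytically computable: a task carries 3 gold pairs, so a
spammer passes one task with probability 1/8 and `k` tasks with `(1/8)^k`.
The probability that a *diligent* worker passes is the product of
`logistic(beta * gap)` over the gold pairs they saw; the test suite checks the
observed pass rate against this closed form (within 3 SE).

What the generator does *not* model: worker learning or fatigue, completion
times, demographic effects, and real-world correlation structure between
workers.  Passing tests therefore demonstrate correctness of the pipeline's
statistics under a clean noise model, not robustness to every behavior of a
real crowd.

## Task design

Every task is 10 pairs: 3 gold pairs drawn from the severe × mild cross
product (expected answer always the severe member) and 7 informative pairs.
Informative sampling measures each candidate pair's gap in crude-rank units
(fraction of N, using per-term win fractions as the crude score) and keeps
pairs with gap in `[min_gap_frac, max_gap_frac]`, defaults 0.05–0.60: pairs
below the window are near-ties that frustrate respondents and carry little
signal; pairs above it are trivially easy and waste budget.  The thresholds
are configuration, not estimates — no principled value is available, and the
defaults were chosen once as a reasonable middle ground.  The two-stage study
generator mirrors practice: a first tranche of uniformly random tasks yields
the crude ranking, the remaining tasks use the informative window.

## Quality control and vote aggregation

The default pass policy is strict: a worker must answer *every* gold pair they
saw correctly (a lenient fraction threshold is exposed as `pass_threshold`).
Gold-pair judgments from passing workers are kept as ranking input — they are
genuine severity judgments, and assigned-vs-usable comparison arithmetic in
studies of this design indicates they count as usable data.  Votes are
aggregated per unordered pair into directed counts `n_ij`, `n_ji`; the
majority direction and the margin `|n_ij − n_ji|` drive the LP.  Tied pairs
are retained in the table (they still document coverage) but contribute no
constraint, since a 1–1 split carries no net preference.

## The ranking LP

Variables: one real score per ADR and one slack per majority constraint.
For each pair with majority winner `w`, loser `l` and margin weight `m_p`:

    s_w − s_l + e_p ≥ δ,    e_p ≥ 0,    minimize Σ_p m_p · e_p

with margin `δ = 1` (any positive value gives the same order; δ only sets the
score scale before normalization).  Real-valued scores make the result
transitive by construction, and the optimal objective equals the weighted
majority mass the final order must overrule.  An alternative `per_vote`
weighting (one constraint per vote direction, weighted by its count) is
exposed for sensitivity analysis.  The solver is scipy's HiGHS interior
point/simplex via `linprog` with a sparse constraint matrix; a 2929-ADR /
58k-pair instance solves in minutes on one CPU.

Two numerical details matter:

* **Degeneracy.**  The slack objective leaves the score vector on a flat
  optimum (any feasible spacing is optimal once the slack pattern is fixed).
  Scores are bounded below by 0 and carry a vanishingly small objective
  penalty (`min_weight / (4 N²)`), which selects the canonical minimal
  solution — each score becomes the longest constraint path from the bottom —
  deterministically.  The penalty is orders of magnitude below the smallest
  constraint weight, so it cannot trade against slack; it only picks one
  vertex of the optimal face.  In the noise-free full-coverage case this
  makes scores exactly linear in rank position, which is what lets the merge
  step recover orders exactly.
* **Order induction.**  Sorting by LP score (ties broken by win fraction,
  then term name) is not always a minimum-violation order: on random 5-ADR
  weighted tournaments it matches the exhaustive-permutation optimum only
  ~55% of the time.  The induced order is therefore polished by a
  deterministic single-item insertion descent against the weighted
  majorities — a standard feedback-arc-set local search whose every move
  strictly reduces the weighted disagreement, so it terminates.  With it, the
  induced order matches the brute-force optimum in ≈ 98% of random 5-ADR
  instances and is never below it.  After refinement, scores are projected
  onto the refined order by a pool-adjacent-violators (antitonic) step so
  that score order and rank order always agree.

Percentiles follow the convention `100 · (N − rank + 1) / N` with rank 1 the
most severe (percentile 100); "severe" means percentile ≥ 95.  Note the
boundary is inclusive: at N = 100 the severe set holds ranks 1–6, because
rank 6 sits exactly at percentile 95.0.

### Sample-and-merge

Sets larger than `sample_size` (default 500) are ranked in pieces: terms are
sorted by crude win fraction; overlapping contiguous blocks of that ordering
(50% overlap), each augmented with `min(25, ⌈0.1 N⌉)` anchor terms spread
evenly over the whole crude range, are solved as independent LPs; each
sample's scores are affinely calibrated onto the crude consensus scale by
least squares over its members; calibrated scores are averaged per term, and
the global order is refined against the full vote table.  Contiguous blocks
concentrate LP effort on hard near-rank comparisons, the overlap plus anchors
stitch the blocks onto one scale, and the whole construction is
deterministic — repeated runs give identical rankings.  An earlier variant
with random (non-contiguous) chunks was measurably less reproducible
(rank correlation ≈ 0.90 between partition seeds) and was replaced.

Disconnected comparison graphs are refused by default; with
`allow_disconnected=True` components are ranked on a common normalized scale
but are genuinely incomparable, and the fitted `components_` attribute flags
them.

## Consistency metrics

* **Triangle violations**: a triplet whose three pairwise majorities form a
  cycle violates transitivity.  Enumeration is exhaustive over triplets whose
  three pairs all have strict majorities (tied pairs exclude the triplet and
  are counted); a `max_triplets` cap subsamples uniformly.  Under uniformly
  random majorities the exact rate is 1/4 (2 cyclic orientations of 8), a
  limit the tests verify by Monte Carlo; a noise-free transitive world gives
  exactly 0.
* **Reproducibility**: duplicate batches (same pair lists, fresh workers) are
  ranked independently and compared by Spearman rank correlation.
* **Full agreement**: among unique pairs judged by ≥ 3 distinct workers, the
  fraction with unanimous votes; 3 independent fair coins agree with
  probability 1/4.
* **Rank-variability classes**: per-ADR rank SD across duplicate batches;
  ADRs are binned into k equal-frequency classes by mean rank and a one-way
  ANOVA asks whether the rank SD differs across classes; the largest
  k ∈ 2..10 with p < 0.001 is reported.  The ANOVA deliberately runs on the
  rank *SDs*, not the ranks themselves: classes are formed by mean rank, so
  an ANOVA of ranks across classes would be significant by construction even
  for pure noise, whereas SD-based classes answer the intended question —
  does rank *stability* vary along the severity scale?  When no k passes
  (e.g., identical ranks in every batch), "no robust classes" is reported.

## Validation and triage

Outcome rates are per-ADR report fractions whose denominator includes
unspecific ("other serious") and outcome-free reports; simulated reports carry
exactly one outcome each (real spontaneous reports can carry several; the
rate code only assumes non-negative counts).  The default outcome link is
`p_death = logistic(−3 + 2.5 · severity)` (death rates ranging ~5–38%) with
severity-independent base rates for the other categories (hospitalization
0.15, other-serious 0.25, ...), leaving the remainder unspecified — chosen to
resemble the composition of spontaneous-report databases, where roughly half
of reports carry no specific outcome.

The lasso regresses the severity score on standardized outcome rates with
10-fold cross-validation (`LassoCV`), choosing the penalty at the CV minimum
(default) or by the 1-SE rule; the leading factor is the largest absolute
standardized coefficient.  `none_specified` is excluded from the predictors
because exclusive outcomes make it an exact linear function of the others.
ADR name matching between tables is exact after case folding and whitespace
normalization — no fuzzy matching, since synthetic fixtures and real term
lists are both exact-string keyed.

Triage utilities are set algebra over the severe set: per-drug distinct
severe-ADR counts aggregated to therapeutic classes (with the display cut
"more than 2 drugs and more than 3 distinct severe ADRs" before correlating
median burden with boxed-warning fraction), per-gene risk as the maximum
percentile among the gene's ADRs (a gene is as risky as its worst reaction;
mean and sum are exposed as alternatives), and novel severe predictions as
(predicted ∖ labeled) ∩ severe per drug.

## Benchmark problem sizes

The experiments in `adrrank.experiments` (run by both the test suite and
`scripts/acceptance.py`) use: 100 random 5-ADR tournaments against a
120-permutation exhaustive oracle; noise-free recovery at N = 60 (single LP)
and N = 200 (merge with `sample_size=60`); noisy recovery at N = 200 with
β = 6 workers, 10% spammers and studies sized for ~20 usable comparisons per
ADR after filtering (65 workers × 5 tasks), reported as the mean Spearman
over 5 replicate studies; filter power at 200 workers × 15 tasks; 10,000
Monte-Carlo draws per combinatorial limit; and validation at 500 ADRs × 200
reports over 5 replicates.  These sizes were chosen so each experiment
completes in seconds while leaving the measured quantities' standard errors
well inside the asserted tolerances.

## Known limitations

* The LP plus local search approximates the minimum weighted feedback arc
  set; it is not exact Kemeny optimization, although it attains the optimum
  in ≈ 98% of small random instances and never undercuts it.
* Sample-and-merge relies on the crude win-fraction ranking to form blocks; a
  term grossly misplaced by the crude ranking is rescued only by the anchors
  and the final global refinement pass.
* Severity scores are ordinal artifacts of the margin LP and the antitonic
  projection; differences between scores should not be read as calibrated
  severity gaps.
* The synthetic generator's clean noise model (independent workers, exclusive
  outcome categories, exact term matching) is deliberately simpler than real
  crowdsourced or spontaneous-report data.
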