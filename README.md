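# adrrank

Severity ranking of adverse drug reactions (ADRs) from crowdsourced pairwise
comparisons.

Drug-safety work constantly needs to know not just *which* ADRs a drug can
cause but *how bad* each one is: triaging thousands of mined drug–ADR
predictions, profiling therapeutic classes, scoring genes by the worst
reaction they are linked to, or damping alert fatigue all require a relative
severity scale, and no such public resource exists.  One practical way to
build one is to ask a crowd to judge many pairs of ADR terms ("which is more
severe: *coma* or *dry mouth*?") and aggregate the judgments into a single
global ranking.  `adrrank` implements that pipeline end to end for
pharmacovigilance researchers and methods developers:

1. **Task design** — 10-pair tasks holding exactly 3 gold (quality-control)
   pairs, built as severe × mild cross products with a known answer, plus 7
   informative random pairs whose crude-rank gap avoids both trivial
   comparisons and near-ties.
2. **Worker quality control** — workers who miss gold questions are removed
   (strict all-correct policy by default); surviving votes are aggregated per
   unordered pair into directed counts and majority margins.
3. **Rank aggregation by linear programming** — every ADR gets a real score
   `s_i`; each majority pair (winner `w`, loser `l`, margin weight `m_p`)
   contributes a constraint with slack, and the LP

   ```
   minimize   Σ_p  m_p · e_p
   subject to s_w − s_l + e_p ≥ δ,   e_p ≥ 0
   ```

   keeps as much of the workers' preferences as possible while the
   real-valued scores enforce transitivity (the triangular inequality) by
   construction.  Large ADR sets are solved by sample-and-merge; the induced
   order is polished by a deterministic feedback-arc-set local search.
4. **Consistency evaluation** — triangle-violation rates, reproducibility
   across duplicate batches, full-agreement rates, rank-variability classes.
5. **Validation and triage** — correlation of the ranking with adverse-event
   outcome rates (death, hospitalization, ...), cross-validated lasso to find
   the leading outcome, severe-set extraction (percentile ≥ 95), ATC-level-2
   class profiles vs. boxed warnings, gene risk scores, and novel-severe-ADR
   triage of predicted drug–ADR associations.

A fully synthetic study generator (latent severities, Bradley–Terry-style
logistic workers, spammers, gold-question structure, outcome tables whose
death rate rises with latent severity) provides ground truth for every stage,
so the whole pipeline is testable without any external data.

## Worked example

```python
import adrrank as ar
from scipy.stats import spearmanr

# a synthetic study: 100 ADRs, 60 workers x 5 tasks, 10% spammers
world = ar.sample_latent_scores(100, seed=1)
study = ar.simulate_study(
    world, n_workers=60, tasks_per_worker=5,
    model=ar.WorkerModel(beta=6.0, spammer_fraction=0.1), seed=1,
)

filt = ar.WorkerQCFilter().fit(study.comparisons)   # gold-question filter
usable = filt.transform(study.comparisons)

ranker = ar.LPSeverityRanker().fit(usable)          # margin-slack LP ranking
print(ranker.ranking_.head(3))

merged = ranker.ranking_.set_index("term").join(world.as_frame().set_index("term"))
print(spearmanr(-merged["rank"], merged["true_score"]).statistic)
```

prints

```
assigned comparisons: 3000
workers passing QC:   50/60
usable comparisons:   2500
   term  score  rank  percentile
ADR_025    1.0     1       100.0
ADR_070    1.0     2        99.0
ADR_030    1.0     3        98.0
Spearman(latent, recovered): 0.944
```

3000 judgments were assigned; the 10 workers who missed a gold question
(spammers plus a few unlucky diligent workers) were dropped, leaving 2500
usable comparisons.  The fitted ranking assigns rank 1 to the most severe
term (percentile 100), and the recovered order correlates at ρ = 0.94 with
the latent truth.  Validating that ranking against a simulated
adverse-event outcome table gives

```
death-rate correlation:      0.898
leading lasso factor:        death
```

— ADRs ranked more severe show higher report death rates, and the
cross-validated lasso picks the death rate as the dominant outcome.

The same pipeline is scriptable from the shell:

```bash
adrrank simulate --n-adrs 200 --n-workers 100 --seed 1 --outdir study/
adrrank qc-filter --comparisons study/comparisons.tsv
adrrank rank --comparisons usable.tsv --out ranking.tsv
adrrank evaluate --comparisons usable.tsv
adrrank validate --ranking ranking.tsv --outcomes study/outcomes.tsv
adrrank triage --ranking ranking.tsv --gene-adr study/gene_adr.tsv
```

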