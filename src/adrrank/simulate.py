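"""Synthetic study generator with known ground truth.

Real crowdsourced severity studies have no observable "true" severity, so
every downstream stage is exercised here against a latent world: each ADR
term carries a true severity score in [0, 1] (1 = most severe), and simulated
workers compare pairs under a Bradley-Terry-style logistic choice rule,

    P(correct choice) = logistic(beta * |score gap|),

with a configurable fraction of spammers who answer uniformly at random
(including on quality-control pairs, so a spammer passes one task's 3 QC
pairs with probability 1/8).  Adverse-event outcome tables are generated with
a death rate that increases with latent severity, which is the signal the
validation stage is supposed to recover.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import design
from .errors import ConfigError, DataError
from .io import OUTCOME_CATEGORIES

PAIRS_PER_TASK = 10
QC_PER_TASK = 3
RANDOM_PER_TASK = PAIRS_PER_TASK - QC_PER_TASK


@dataclass
class LatentWorld:
    """Ground-truth severities for a set of ADR terms."""

    terms: list[str]
    scores: np.ndarray
    seed: int

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.terms) != len(self.scores):
            raise ConfigError("terms and scores must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise ConfigError("latent scores must be finite")
        self._index = {t: i for i, t in enumerate(self.terms)}

    @property
    def n_adrs(self) -> int:
        return len(self.terms)

    def score_of(self, term: str) -> float:
        try:
            return float(self.scores[self._index[term]])
        except KeyError:
            raise DataError(f"unknown ADR term {term!r}") from None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "true_score": self.scores})


@dataclass
class WorkerModel:
    """Noise model for simulated workers.

    beta is the discrimination of the logistic choice rule (0 = coin flips,
    large = near-deterministic); spammer_fraction of workers ignore the pair
    content entirely and answer uniformly.
    """

    beta: float = 6.0
    spammer_fraction: float = 0.1

    def __post_init__(self):
        if self.beta < 0:
            raise ConfigError("beta must be non-negative")
        if not 0 <= self.spammer_fraction <= 1:
            raise ConfigError("spammer_fraction must lie in [0, 1]")


@dataclass
class OutcomeLink:
    """How outcome probabilities depend on latent severity.

    The death probability is logistic(intercept + slope * score); the other
    categories are severity-independent with the given base rates, and any
    remaining mass goes to ``none_specified``.  Categories are mutually
    exclusive per simulated report.
    """

    death_intercept: float = -3.0
    death_slope: float = 2.5
    base_rates: dict = field(
        default_factory=lambda: {
            "disability": 0.03,
            "life_threatening": 0.05,
            "required_intervention": 0.02,
            "hospitalization": 0.15,
            "congenital_anomaly": 0.01,
            "other_serious": 0.25,
        }
    )

    def probabilities(self, score: float) -> np.ndarray:
        """Per-category probabilities in OUTCOME_CATEGORIES order."""
        p_death = float(expit(self.death_intercept + self.death_slope * score))
        probs = {"death": p_death, **{k: float(v) for k, v in self.base_rates.items()}}
        specified = sum(probs.get(c, 0.0) for c in OUTCOME_CATEGORIES[:-1])
        probs["none_specified"] = 1.0 - specified
        vec = np.array([probs.get(c, 0.0) for c in OUTCOME_CATEGORIES])
        if (vec < -1e-12).any() or (vec > 1 + 1e-12).any():
            raise ConfigError(f"outcome probabilities outside [0, 1]: {probs}")
        return np.clip(vec, 0.0, 1.0)


@dataclass
class SyntheticStudy:
    """A complete simulated study: comparisons plus ground-truth labels."""

    world: LatentWorld
    comparisons: pd.DataFrame
    workers: pd.DataFrame  # worker_id, batch_id, is_spammer


def sample_latent_scores(n_adrs: int, distribution="uniform", seed: int = 0) -> LatentWorld:
    """Draw a latent world of ``n_adrs`` true severities.

    ``distribution`` is either ``"uniform"`` (uniform on [0, 1]) or a tuple
    ``("beta", a, b)``.
    """
    if n_adrs < 2:
        raise ConfigError("a study needs at least 2 ADRs")
    rng = np.random.default_rng(seed)
    if distribution == "uniform" or distribution == ("uniform",):
        scores = rng.uniform(0.0, 1.0, size=n_adrs)
    elif isinstance(distribution, tuple) and distribution[0] == "beta":
        _, a, b = distribution
        scores = rng.beta(a, b, size=n_adrs)
    else:
        raise ConfigError(f"unknown distribution spec {distribution!r}")
    width = len(str(n_adrs))
    terms = [f"ADR_{i:0{width}d}" for i in range(1, n_adrs + 1)]
    return LatentWorld(terms=terms, scores=scores, seed=seed)


def simulate_response(
    worker_kind: str,
    pair: tuple[str, str],
    world: LatentWorld,
    model: WorkerModel,
    rng: np.random.Generator,
) -> str:
    """One worker's choice ("a" or "b") for one presented pair.

    A diligent worker picks the truly more severe member with probability
    logistic(beta * |gap|); a spammer flips a fair coin.
    """
    term_a, term_b = pair
    if worker_kind == "spammer":
        return "a" if rng.random() < 0.5 else "b"
    if worker_kind != "diligent":
        raise ConfigError(f"unknown worker kind {worker_kind!r}")
    gap = world.score_of(term_a) - world.score_of(term_b)
    p_a = expit(model.beta * gap)
    return "a" if rng.random() < p_a else "b"


def simulate_study(
    world: LatentWorld,
    n_workers: int,
    tasks_per_worker: int,
    model: WorkerModel | None = None,
    qc_severe: list[str] | None = None,
    qc_mild: list[str] | None = None,
    n_batches: int = 1,
    seed: int = 0,
) -> SyntheticStudy:
    """Simulate a full crowdsourced study.

    Every task holds exactly 3 quality-control pairs (a severe vs. a mild term
    from the QC pools, expected answer the severe member) and 7 random pairs.
    ``n_batches`` > 1 replicates the same task designs across batches answered
    by fresh workers, which is what reproducibility evaluation needs: duplicate
    batches share their pair lists but not their workers.
    """
    model = model or WorkerModel()
    rng = np.random.default_rng(seed)
    if qc_severe is None or qc_mild is None:
        qc_severe, qc_mild = default_qc_sets(world)
    qc_pool = design.build_qc_pairs(qc_severe, qc_mild)
    unknown = (set(qc_severe) | set(qc_mild)) - set(world.terms)
    if unknown:
        raise ConfigError(f"QC terms not in world: {sorted(unknown)}")

    n_tasks = n_workers * tasks_per_worker
    tasks = design.assemble_tasks(
        qc_pool,
        candidate_terms=world.terms,
        n_tasks=n_tasks,
        rng=rng,
    )

    comp_rows: list[dict] = []
    worker_rows: list[dict] = []
    for batch_idx in range(1, n_batches + 1):
        batch_id = f"batch{batch_idx}"
        _respond_to_tasks(
            tasks, tasks_per_worker, world, model, rng,
            batch_id=batch_id, worker_prefix=f"{batch_id}_worker",
            comp_rows=comp_rows, worker_rows=worker_rows,
        )
    comparisons = pd.DataFrame(comp_rows)
    workers = pd.DataFrame(worker_rows)
    return SyntheticStudy(world=world, comparisons=comparisons, workers=workers)


def _respond_to_tasks(
    tasks, tasks_per_worker, world, model, rng, batch_id, worker_prefix, comp_rows, worker_rows
):
    """Have fresh simulated workers answer the given tasks, tasks_per_worker each."""
    n_workers = -(-len(tasks) // tasks_per_worker)
    idx = 0
    for w in range(n_workers):
        worker_id = f"{worker_prefix}{w + 1:04d}"
        is_spammer = rng.random() < model.spammer_fraction
        kind = "spammer" if is_spammer else "diligent"
        worker_rows.append(
            {"worker_id": worker_id, "batch_id": batch_id, "is_spammer": is_spammer}
        )
        for _ in range(tasks_per_worker):
            if idx >= len(tasks):
                break
            task = tasks[idx]
            idx += 1
            for pair in task.pairs:
                chosen = simulate_response(kind, (pair.adr_a, pair.adr_b), world, model, rng)
                comp_rows.append(
                    {
                        "worker_id": worker_id,
                        "batch_id": batch_id,
                        "adr_a": pair.adr_a,
                        "adr_b": pair.adr_b,
                        "chosen": chosen,
                        "is_qc": pair.is_qc,
                        "qc_expected": pair.qc_expected,
                    }
                )


def simulate_two_stage_study(
    world: LatentWorld,
    n_workers: int,
    tasks_per_worker: int,
    model: WorkerModel | None = None,
    qc_severe: list[str] | None = None,
    qc_mild: list[str] | None = None,
    first_stage_fraction: float = 0.3,
    min_gap_frac: float = 0.05,
    max_gap_frac: float = 0.60,
    seed: int = 0,
) -> SyntheticStudy:
    """Simulate a study with informative-pair task design.

    Mirrors how real comparison batches are constructed: a first stage of
    uniformly random pairs yields a crude (win-fraction) ranking, and the
    remaining tasks sample pairs whose crude-rank gap avoids both trivial
    comparisons and near-ties.  All tasks keep the 3 QC + 7 random structure.
    """
    model = model or WorkerModel()
    if not 0 < first_stage_fraction < 1:
        raise ConfigError("first_stage_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if qc_severe is None or qc_mild is None:
        qc_severe, qc_mild = default_qc_sets(world)
    qc_pool = design.build_qc_pairs(qc_severe, qc_mild)

    n_tasks = n_workers * tasks_per_worker
    n_first = max(1, int(round(first_stage_fraction * n_tasks)))
    tasks1 = design.assemble_tasks(
        qc_pool, candidate_terms=world.terms, n_tasks=n_first, rng=rng
    )
    comp_rows: list[dict] = []
    worker_rows: list[dict] = []
    _respond_to_tasks(
        tasks1, tasks_per_worker, world, model, rng,
        batch_id="batch1", worker_prefix="batch1_workerA",
        comp_rows=comp_rows, worker_rows=worker_rows,
    )
    stage1 = pd.DataFrame(comp_rows)
    crude = design.crude_scores(stage1[~stage1["is_qc"]])
    for term in world.terms:  # unseen terms sit mid-scale
        crude.setdefault(term, 0.5)

    n_second = n_tasks - n_first
    if n_second > 0:
        pairs = design.sample_informative_pairs(
            world.terms, crude, n=design.RANDOM_PER_TASK * n_second,
            min_gap_frac=min_gap_frac, max_gap_frac=max_gap_frac, rng=rng,
        )
        tasks2 = design.assemble_tasks(
            qc_pool, candidate_pairs=pairs, n_tasks=n_second, rng=rng,
            replace=len(pairs) < design.RANDOM_PER_TASK * n_second,
        )
        _respond_to_tasks(
            tasks2, tasks_per_worker, world, model, rng,
            batch_id="batch1", worker_prefix="batch1_workerB",
            comp_rows=comp_rows, worker_rows=worker_rows,
        )
    return SyntheticStudy(
        world=world,
        comparisons=pd.DataFrame(comp_rows),
        workers=pd.DataFrame(worker_rows),
    )


def default_qc_sets(world: LatentWorld, n_each: int = 4) -> tuple[list[str], list[str]]:
    """Pick QC pools from the latent extremes: top-``n_each`` and bottom-``n_each`` terms.

    Mirrors how gold questions are built in practice — obviously severe vs.
    obviously mild terms — and guarantees a large score gap, so diligent
    workers almost always answer them correctly.
    """
    if world.n_adrs < 2 * n_each + 2:
        raise ConfigError("world too small for default QC sets")
    order = np.argsort(world.scores)
    mild = [world.terms[i] for i in order[:n_each]]
    severe = [world.terms[i] for i in order[-n_each:]]
    return severe, mild


def simulate_full_coverage(
    world: LatentWorld,
    model: WorkerModel | None = None,
    votes_per_pair: int = 1,
    seed: int = 0,
    batch_id: str = "batch1",
) -> pd.DataFrame:
    """Comparisons covering every unordered pair of the world, no QC structure.

    Used for recovery experiments where complete pair coverage is the point.
    One synthetic diligent worker answers each vote.
    """
    model = model or WorkerModel(spammer_fraction=0.0)
    rng = np.random.default_rng(seed)
    rows = []
    n = world.n_adrs
    worker = 0
    for i in range(n):
        for j in range(i + 1, n):
            for _ in range(votes_per_pair):
                worker += 1
                a, b = world.terms[i], world.terms[j]
                if rng.random() < 0.5:  # randomize presentation side
                    a, b = b, a
                chosen = simulate_response("diligent", (a, b), world, model, rng)
                rows.append(
                    {
                        "worker_id": f"{batch_id}_worker{worker:07d}",
                        "batch_id": batch_id,
                        "adr_a": a,
                        "adr_b": b,
                        "chosen": chosen,
                        "is_qc": False,
                        "qc_expected": None,
                    }
                )
    return pd.DataFrame(rows)


def simulate_reports(
    world: LatentWorld,
    reports_per_adr: int = 200,
    link: OutcomeLink | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-ADR adverse-event outcome counts with severity-linked death rates.

    Each of ``reports_per_adr`` reports gets exactly one outcome category
    (multinomial draw), so per-ADR counts always sum to ``reports_per_adr``.
    """
    link = link or OutcomeLink()
    if reports_per_adr < 0:
        raise ConfigError("reports_per_adr must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for term, score in zip(world.terms, world.scores):
        probs = link.probabilities(score)
        counts = rng.multinomial(reports_per_adr, probs / probs.sum())
        rows.append({"adr": term, **dict(zip(OUTCOME_CATEGORIES, counts.tolist()))})
    return pd.DataFrame(rows, columns=["adr", *OUTCOME_CATEGORIES])


def simulate_drug_universe(
    world: LatentWorld,
    n_drugs: int = 60,
    n_classes: int = 10,
    adrs_per_drug: float = 30.0,
    severity_bias_range: tuple[float, float] = (0.0, 3.0),
    warning_intercept: float = -2.0,
    warning_slope: float = 0.5,
    severe_percentile: float = 95.0,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Drug-ADR associations, ATC-level-2-style classes and boxed warnings.

    Each therapeutic class gets a severity bias: its drugs sample ADRs with
    weights proportional to exp(bias * true score), so classes genuinely differ
    in how many severe ADRs their drugs carry.  A drug's boxed-warning
    probability is logistic(intercept + slope * severe-ADR count), which makes
    the class-level correlation between severe-ADR burden and warning fraction
    positive by construction.
    """
    rng = np.random.default_rng(seed)
    if n_classes < 1 or n_drugs < 1:
        raise ConfigError("need at least one class and one drug")
    scores = world.scores
    cutoff = np.quantile(scores, severe_percentile / 100.0)
    class_ids = [f"ATC_{i:02d}" for i in range(1, n_classes + 1)]
    class_bias = dict(zip(class_ids, rng.uniform(*severity_bias_range, size=n_classes)))
    drug_rows, assoc_rows, warn_rows = [], [], []
    for d in range(1, n_drugs + 1):
        drug = f"DRUG_{d:03d}"
        cls = class_ids[int(rng.integers(n_classes))]
        drug_rows.append({"subject": drug, "atc2": cls})
        k = min(world.n_adrs, max(1, int(rng.poisson(adrs_per_drug))))
        weights = np.exp(class_bias[cls] * scores)
        weights /= weights.sum()
        idx = rng.choice(world.n_adrs, size=k, replace=False, p=weights)
        n_severe = 0
        for i in idx:
            assoc_rows.append({"subject": drug, "adr": world.terms[i]})
            if scores[i] >= cutoff:
                n_severe += 1
        p_warn = float(expit(warning_intercept + warning_slope * n_severe))
        warn_rows.append({"subject": drug, "boxed_warning": bool(rng.random() < p_warn)})
    return {
        "drug_adr": pd.DataFrame(assoc_rows),
        "drug_class": pd.DataFrame(drug_rows),
        "box_warning": pd.DataFrame(warn_rows),
    }


def simulate_gene_associations(
    world: LatentWorld,
    n_genes: int = 40,
    adrs_per_gene: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Literature-style gene-ADR association table (uniform over ADRs)."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(1, n_genes + 1):
        gene = f"GENE_{g:03d}"
        k = min(world.n_adrs, max(1, int(rng.poisson(adrs_per_gene))))
        for i in rng.choice(world.n_adrs, size=k, replace=False):
            rows.append({"subject": gene, "adr": world.terms[i]})
    return pd.DataFrame(rows)


def simulate_predicted_associations(
    world: LatentWorld,
    labeled: pd.DataFrame,
    extra_per_drug: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mined-prediction-style table: the labeled associations plus novel ones."""
    rng = np.random.default_rng(seed)
    rows = [dict(r) for r in labeled[["subject", "adr"]].to_dict("records")]
    for drug, grp in labeled.groupby("subject"):
        known = set(grp["adr"])
        pool = [t for t in world.terms if t not in known]
        k = min(len(pool), int(rng.poisson(extra_per_drug)))
        if k:
            for t in rng.choice(pool, size=k, replace=False):
                rows.append({"subject": drug, "adr": t})
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True)
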