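import numpy as np
import pandas as pd
import pytest

import adrrank as ar


def make_comparisons(rows):
    """Build a comparison frame from (worker, batch, a, b, chosen, is_qc, expected) tuples."""
    return pd.DataFrame(
        rows,
        columns=["worker_id", "batch_id", "adr_a", "adr_b", "chosen", "is_qc", "qc_expected"],
    )


def perfect_ranking(world):
    """Ranking frame built directly from a latent world's true scores."""
    order = np.argsort(-world.scores, kind="stable")
    n = world.n_adrs
    return pd.DataFrame(
        {
            "term": [world.terms[i] for i in order],
            "score": world.scores[order],
            "rank": np.arange(1, n + 1),
            "percentile": ar.to_percentiles(np.arange(1, n + 1), n),
        }
    )


@pytest.fixture(scope="session")
def small_world():
    return ar.sample_latent_scores(20, seed=7)


@pytest.fixture(scope="session")
def noisy_study():
    """A moderate study with spammers, reused by QC and ranking tests."""
    world = ar.sample_latent_scores(60, seed=3)
    study = ar.simulate_study(
        world,
        n_workers=50,
        tasks_per_worker=5,
        model=ar.WorkerModel(beta=6.0, spammer_fraction=0.1),
        seed=3,
    )
    return study
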