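"""Shared fixtures.

Training-based fixtures are session-scoped so the (CPU-minutes) cost of
training RNN cohorts is paid once and shared between the property tests and
the acceptance tests.
"""

import numpy as np
import pytest

from delayti import behavior, models, training
from delayti.synthdata import make_item_panel
from delayti.task import TrialTiming

COHORT_SIZE = 3
COHORT_CELLS = (
    ("f-RNN", "highest"),
    ("f-RNN", "lowest"),
    ("r-RNN", "highest"),
)


def train_instance(variant, regime, seed, **cfg_kwargs):
    panel = make_item_panel(7, 100, seed)
    params = models.init_network(variant, regime, seed=seed)
    cfg = training.TrainingConfig(seed=seed, **cfg_kwargs)
    report = training.train_rnn(params, panel, cfg)
    return dict(params=params, panel=panel, report=report, seed=seed)


@pytest.fixture(scope="session")
def trained_cohorts():
    """3 trained instances per (variant, regime) cell, keeping only full
    generalizers (training extra seeds if needed, as the source filtering
    does)."""
    cohorts = {}
    for variant, regime in COHORT_CELLS:
        instances = []
        seed = 0
        while len(instances) < COHORT_SIZE and seed < 4 * COHORT_SIZE:
            inst = train_instance(variant, regime, seed)
            if inst["report"].generalization["full_generalizer"]:
                instances.append(inst)
            seed += 1
        cohorts[f"{variant}_{regime}"] = instances
    return cohorts


@pytest.fixture(scope="session")
def behavior_cohorts(trained_cohorts):
    """Titrated-noise behavioral records for each trained instance.

    Uses a reduced simulation count and coarse-to-fine titration to stay
    within the suite's runtime budget; the statistics used by the tests are
    cohort-level signs and orderings, which are insensitive to this.
    """
    timing = TrialTiming.basic()
    out = {}
    for cell, instances in trained_cohorts.items():
        recs = []
        for inst in instances:
            try:
                noise = behavior.titrate_noise(
                    inst["params"], inst["panel"], timing,
                    n_per_type=100, seed=inst["seed"], coarse_step=10,
                )
            except behavior.TitrationError:
                continue
            records = behavior.simulate_behavior(
                inst["params"], inst["panel"], noise, timing,
                n_per_type=200, seed=inst["seed"] + 10_000,
            )
            summary = behavior.summarize_behavior(records, noise_sd=noise)
            recs.append(dict(noise=noise, records=records, summary=summary,
                             seed=inst["seed"]))
        out[cell] = recs
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
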