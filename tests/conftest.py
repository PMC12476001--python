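import numpy as np
import pandas as pd
import pytest

import trialwise as tw
from trialwise._logp import TrialData


@pytest.fixture(scope="session")
def small_table():
    """3 participants, full 176-trial design, ~10% missing."""
    design = tw.generate_design(3, seed=7)
    truth = tw.default_true_params(3, seed=8)
    table = tw.simulate_amplitudes(design, truth, seed=9)
    return tw.apply_missingness(table, 0.10, seed=10)


@pytest.fixture(scope="session")
def small_truth():
    return tw.default_true_params(3, seed=8)


@pytest.fixture(scope="session")
def small_data(small_table):
    return TrialData(small_table)


@pytest.fixture(scope="session")
def tiny_fit(small_table):
    """A quick M1 fit reused by inference/analysis tests."""
    config = tw.SamplerConfig(n_chains=2, n_warmup=250, n_draws=250, seed=42)
    return tw.fit_model("m1", small_table, config, check_convergence=False)


def make_participant_rows(cues, paired, participant=1, block="ACQ1"):
    """Minimal one-participant trial-table slice."""
    return pd.DataFrame({
        "participant": participant,
        "trial": np.arange(1, len(cues) + 1),
        "block": block,
        "cue": cues,
        "paired": paired,
    })
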