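import warnings

import numpy as np
import pytest

import sees

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def instrument():
    return sees.load_instrument()


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated subscale table plus its generating truth."""
    cfg = sees.SimulationConfig(K=15, items=4, seed=101, na_probability=0.1)
    rng = np.random.default_rng(101)
    truth = sees.draw_truth(cfg, rng)
    table = sees.simulate_responses(truth, cfg, rng)
    return cfg, truth, table


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A fast consensus fit on the small simulated table (shared)."""
    cfg, truth, table = small_sim
    inst = sees.synthetic_instrument(cfg)
    mc = sees.ModelConfig(seed=5, warmup=400, draws_per_chain=300)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sees.model.ConvergenceWarning)
        fit = sees.fit_consensus(table, inst, "subjective_evidence", mc)
    return inst, mc, fit
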