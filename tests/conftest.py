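import pytest

from sipracs import (
    aggregate_window_abundance,
    identify_windows,
    soil_gradient_config,
    simulate_gradient_experiment,
)


@pytest.fixture(scope="session")
def sip_experiment():
    """Default synthetic SIP experiment: 100 taxa, two fully labelled, seed 1."""
    cfg = soil_gradient_config(seed=1)
    run12, run13, table = simulate_gradient_experiment(cfg)
    return cfg, run12, run13, table


@pytest.fixture(scope="session")
def sip_windows(sip_experiment):
    _, run12, run13, _ = sip_experiment
    return identify_windows(run12, run13)


@pytest.fixture(scope="session")
def sip_aggregates(sip_experiment, sip_windows):
    _, run12, run13, table = sip_experiment
    return aggregate_window_abundance(table, sip_windows, {"12C": run12, "13C": run13})
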