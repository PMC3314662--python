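import pytest

from tlr4sim import network, scenarios, synthetic
from tlr4sim.synthetic import COMPLEX_CONSTITUENTS


@pytest.fixture(scope="session")
def reference_table():
    return synthetic.table2_fixture()


@pytest.fixture(scope="session")
def scenario_table(reference_table):
    """Scenario table rebuilt through the construction rules, seeded with
    ratio summaries recovered from the packaged reference rows."""
    ref = reference_table
    summaries = {
        r.species: scenarios.summary_from_multipliers(
            r.r_min_resp, r.r_max_resp, r.r_avg_resp, r.sensitivity)
        for r in ref.itertuples() if r.species not in COMPLEX_CONSTITUENTS
    }
    return scenarios.build_scenario_table(
        ratio_sets={},
        sensitivities=dict(zip(ref["species"], ref["sensitivity"])),
        base_concs=dict(zip(ref["species"], ref["base_conc"])),
        constituent_summaries=summaries,
    )


@pytest.fixture(scope="session")
def base_model():
    return network.build_default_network()


@pytest.fixture(scope="session")
def base_timecourse(base_model):
    return network.simulate(base_model)


@pytest.fixture(scope="session")
def scenario_metrics(scenario_table):
    out = {}
    for name in ("base", "min_resp", "avg_resp", "max_resp"):
        model = network.build_default_network(scenario_table, scenario=name)
        out[name] = network.peak_metrics(network.simulate(model))
    return out
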