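import numpy as np
import pytest

from mucodyn import ModelParams, ScenarioConfig, scenario_presets, simulate


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def presets():
    return scenario_presets()


@pytest.fixture(scope="session")
def scenario_runs(params, presets):
    """Simulated trajectories for all six study scenarios (shared)."""
    return {name: simulate(sc, params) for name, sc in presets.items()}


@pytest.fixture(scope="session")
def live_mixture_tables():
    """Monoculture references and a labeled 50/50 co-culture mixture of live
    events at three separations, shared by the classification tests."""
    from mucodyn.synth import generate_flow_events, make_population_spec

    out = {}
    for sep in (2.0, 4.0, 6.0):
        mono_bt = generate_flow_events(make_population_spec(
            sep, {"BT_live": 1.0}, total_events=1500, seed=101))
        mono_ri = generate_flow_events(make_population_spec(
            sep, {"RI_live": 1.0}, total_events=1500, seed=102))
        co = generate_flow_events(make_population_spec(
            sep, {"BT_live": 0.5, "RI_live": 0.5}, total_events=800, seed=103))
        out[sep] = (mono_bt, mono_ri, co)
    return out
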