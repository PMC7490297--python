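import numpy as np
import pandas as pd
import pytest

import sunfleck as sf


@pytest.fixture(scope="session")
def kin() -> sf.LeafKinetics:
    return sf.LeafKinetics()


@pytest.fixture(scope="session")
def params_ln() -> sf.FvCBParams:
    """Low-nitrogen Koshihikari-like capacities."""
    return sf.FvCBParams(Vcmax=85.0, Jmax=125.0)


@pytest.fixture(scope="session")
def leaf(params_ln) -> sf.SimLeaf:
    return sf.SimLeaf(fvcb=params_ln)


@pytest.fixture(scope="session")
def step_regime() -> sf.LightRegime:
    return sf.step_light_protocol()


@pytest.fixture(scope="session")
def induction_trace(step_regime, leaf) -> sf.GasExchangeTrace:
    """Noiseless simulated step-change experiment at 400 ppm."""
    return sf.simulate_leaf(step_regime, leaf, co2=400.0,
                            noise=sf.NoiseModel.none())


def make_trace(time, A, gs=0.3, Ci=300.0, Ca=400.0, ppfd=1500.0, **extra):
    """Hand-built gas-exchange trace from scalars or arrays."""
    time = np.asarray(time, dtype=float)
    n = len(time)

    def col(v):
        return np.full(n, v, dtype=float) if np.ndim(v) == 0 else np.asarray(v, float)

    data = {
        "time_s": time,
        "ppfd": col(ppfd),
        "A": col(A),
        "gs": col(gs),
        "Ci": col(Ci),
        "Ca": col(Ca),
        "Tleaf": col(28.0),
    }
    for k, v in extra.items():
        data[k] = col(v)
    return sf.GasExchangeTrace(pd.DataFrame(data))
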