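import numpy as np
import pytest

from sunbedban import ParameterSet, load_config, make_population_tables
from sunbedban.population import PopulationTables, SEXES, ARMS


@pytest.fixture(scope="session")
def config():
    return load_config(None)


@pytest.fixture(scope="session")
def params(config):
    return config.params


@pytest.fixture(scope="session")
def tables(params):
    return make_population_tables(params)


def build_tables(
    params: ParameterSet,
    mortality: float | np.ndarray = 0.0,
    melanoma: float | np.ndarray = 0.0,
    kc: float | np.ndarray = 0.0,
    norm: float | np.ndarray = 0.929,
    everuse: float | np.ndarray = 0.0,
) -> PopulationTables:
    """Hand-built table set with constant (or given) columns, for closed-form
    and oracle checks where the synthetic generator's shapes would get in
    the way."""
    ages = np.arange(18, 18 + params.n_cycles + 1)

    def col(v):
        return np.broadcast_to(np.asarray(v, dtype=float), ages.shape).copy()

    return PopulationTables(
        ages=ages,
        all_cause_mortality={s: col(mortality) for s in SEXES},
        melanoma_incidence={s: col(melanoma) for s in SEXES},
        kc_incidence={s: col(kc) for s in SEXES},
        eq5d_norm={s: col(norm) for s in SEXES},
        everuse={(s, a): col(everuse) for s in SEXES for a in ARMS},
    )
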