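import numpy as np
import pytest

from hydrofda.io_ingest import season_grid
from hydrofda.synthetic import SyntheticScenario, generate


@pytest.fixture(scope="session")
def grid():
    """The standard 62-node daily Dec-Jan grid."""
    return season_grid(2000)


@pytest.fixture(scope="session")
def default_dataset():
    """One realisation of the default 17-season, 3-stream scenario."""
    return generate(SyntheticScenario(seed=42))


@pytest.fixture(scope="session")
def small_scenario():
    """Light scenario for pipeline-level tests (5 bio seasons)."""
    return SyntheticScenario(seed=7, n_seasons=5)


def design_rows_from_dataset(ds, variable="ppr", clip=False):
    """Lag-1 design rows pairing responses with the *true* latent curves."""
    from hydrofda.responses import LaggedDesignRow, SeasonalResponse

    lat = ds.true_latent_objects()
    streams = ds.scenario.streams
    rows = []
    for s, y in sorted(ds.responses[variable].items()):
        rows.append(
            LaggedDesignRow(
                response=SeasonalResponse(variable, s, max(y, 0.0) if clip else y, 1),
                covariates={st: lat[(st, s - 1)] for st in streams},
            )
        )
    return rows
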