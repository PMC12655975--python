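import numpy as np
import pandas as pd
import pytest

import pterisk as pk
from pterisk.core_io import DistributionSpec, Medium, Population


@pytest.fixture(scope="session")
def refs():
    return pk.default_reference_bundle()


@pytest.fixture(scope="session")
def refs_point(refs):
    """Bundle with every exposure distribution collapsed to its central value."""
    exposure = {
        pop: {
            med: {
                name: DistributionSpec(kind="point", params={"value": spec.central()})
                for name, spec in params.items()
            }
            for med, params in media.items()
        }
        for pop, media in refs.exposure.items()
    }
    return refs.model_copy(update={"exposure": exposure})


@pytest.fixture(scope="session")
def soil_table():
    """Small synthetic soil table with known 3-source structure."""
    profiles = pk.preset("soil_3source")
    table, _ = pk.generate_mixture(profiles, 12, noise_cv=20.0, seed=11)
    return table


@pytest.fixture
def water_csv(tmp_path):
    df = pd.DataFrame(
        np.array(
            [
                [2.9, 1.2, 50.0, 48.0, 900.0, 1.6, 230.0, 3.2, 22.0, 1.2],
                [0.5, 0.3, 10.0, 9.0, 100.0, 0.4, 60.0, 0.8, 4.0, 0.3],
                [8.0, 3.5, 150.0, 140.0, 2500.0, 4.5, 700.0, 9.0, 60.0, 3.5],
            ]
        ),
        columns=list(pk.ELEMENTS),
        index=["W1", "W2", "W3"],
    )
    df.index.name = "site"
    path = tmp_path / "water.csv"
    df.to_csv(path)
    return path
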