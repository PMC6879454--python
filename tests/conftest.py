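import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import txoverlap as tx

settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def strong_study() -> tx.SimulatedDataset:
    """A small study where every planted DE gene is recoverable with certainty."""
    config = tx.StudyConfig(
        n_genes=400,
        n_case=10,
        n_control=10,
        n_de=40,
        effect_size=4.0,
        noise_sd=0.1,
        seed=11,
    )
    return tx.simulate_dataset(config)


@pytest.fixture()
def toy_matrix() -> tx.ExpressionMatrix:
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["P1", "P2", "P3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return tx.ExpressionMatrix(values)


def make_signature(label, entries, taxon="9606"):
    """entries: dict gene -> (direction, p)."""
    return tx.DiseaseSignature(
        label=label,
        taxon=taxon,
        directions={g: d for g, (d, _) in entries.items()},
        pvalues={g: p for g, (_, p) in entries.items()},
    )
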