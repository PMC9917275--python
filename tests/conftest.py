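import numpy as np
import pandas as pd
import pytest

from wrenprey import AllometricCoefficient, generate_study, nominal_config


@pytest.fixture(scope="session")
def nominal_bundle():
    """One nominal synthetic study, shared across tests (seed 11)."""
    return generate_study(nominal_config(11))


@pytest.fixture(scope="session")
def synthetic_registry():
    """Simple synthetic allometric coefficients covering the default orders."""
    taxa = [
        "Araneae", "Coleoptera", "Diptera", "Hemiptera",
        "Hymenoptera", "Isopoda", "Lepidoptera", "Orthoptera",
    ]
    return {
        t: AllometricCoefficient(t, a=0.01 * (i + 1), b=2.0 + 0.1 * i)
        for i, t in enumerate(taxa)
    }


@pytest.fixture()
def simple_records():
    """Tiny hand-checkable arthropod record table: one territory, two blocks,
    two time blocks, one element/stratum/taxon."""
    rows = []
    for block, time_block, length in [(1, 1, 2.0), (2, 1, 3.0), (1, 2, 4.0), (2, 2, 5.0)]:
        rows.append(
            dict(site="S1", territory="S1:T1", block=block, time_block=time_block,
                 habitat_element="ARCA", stratum="canopy", taxon="Araneae",
                 count=1, body_length_mm=length)
        )
    return pd.DataFrame(rows)


@pytest.fixture()
def identity_registry():
    """mass = length (a=1, b=1) for direct arithmetic checks."""
    return {t: AllometricCoefficient(t, 1.0, 1.0) for t in ["Araneae", "Lepidoptera"]}
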