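import pandas as pd
import pytest

from pfasrisk import chem


@pytest.fixture(scope="session")
def registry():
    return chem.load_registry()


@pytest.fixture(scope="session")
def fragment_rules():
    return chem.load_fragment_rules()


@pytest.fixture(scope="session")
def occurrence(registry):
    """Occurrence table (DF fraction, max ng/L) from the packaged registry."""
    return pd.DataFrame(
        {
            "detection_frequency": [r.detection_frequency for r in registry],
            "max_concentration": [r.max_concentration for r in registry],
        },
        index=pd.Index([r.acronym for r in registry], name="compound"),
    )
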