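import numpy as np
import pandas as pd
import pytest

from modelmatch.de_io import DETable


def make_detable(values: dict[str, float], dataset_id: str = "t") -> DETable:
    """Build a DETable directly from gene -> signed_sig values.

    direction is the sign of the value (+1 for zero), and p is chosen as
    10**(-|value|) so the signed significance round-trips exactly.
    """
    genes = list(values)
    s = np.array([values[g] for g in genes], dtype=float)
    direction = np.where(s >= 0, 1, -1)
    return DETable(
        dataset_id=dataset_id,
        data=pd.DataFrame(
            {
                "gene": genes,
                "direction": direction,
                "p": np.power(10.0, -np.abs(s)),
                "signed_sig": s,
            }
        ),
    )


@pytest.fixture
def detable_factory():
    return make_detable
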