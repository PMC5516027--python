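import pandas as pd
import pytest

from panflux.families import FamilyMatrix


@pytest.fixture
def three_strain_matrix() -> FamilyMatrix:
    """Presence patterns a:111, b:110, c:100 over strains S1..S3."""
    counts = pd.DataFrame(
        {"a": [1, 1, 1], "b": [1, 1, 0], "c": [1, 0, 0]},
        index=["S1", "S2", "S3"],
    )
    return FamilyMatrix(counts=counts)


@pytest.fixture
def chain_matrix() -> FamilyMatrix:
    """F={a,b}, G={b,c}, H={c,d}: the hand-enumerable accumulation fixture."""
    counts = pd.DataFrame(
        [[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]],
        index=["F", "G", "H"],
        columns=list("abcd"),
    )
    return FamilyMatrix(counts=counts)
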