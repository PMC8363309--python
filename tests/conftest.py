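import numpy as np
import pandas as pd
import pytest

import stepblup as sb


def random_pedigree_frame(n: int, rng: np.random.Generator,
                          n_founders: int = 5, inbred: bool = True) -> pd.DataFrame:
    """Random valid pedigree frame (parents drawn among earlier animals)."""
    rows = []
    for i in range(n):
        if i < n_founders or rng.random() < 0.15:
            s = d = "0"
        else:
            s = str(int(rng.integers(0, i)) + 1)
            d = str(int(rng.integers(0, i)) + 1)
            if s == d and not inbred:
                d = "0"
        rows.append((str(i + 1), s, d, 2000 + i // 10))
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year"])


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def trio_pedigree():
    """Two unrelated founders and their offspring."""
    return sb.pedigree_from_frame(
        pd.DataFrame(
            {
                "animal": ["1", "2", "3"],
                "sire": ["0", "0", "1"],
                "dam": ["0", "0", "2"],
                "birth_year": [2000, 2000, 2001],
            }
        )
    )


@pytest.fixture
def fullsib_pedigree():
    """Founders 1,2; full sibs 3,4; inbred offspring 5 of the sib mating."""
    return sb.pedigree_from_frame(
        pd.DataFrame(
            {
                "animal": ["1", "2", "3", "4", "5"],
                "sire": ["0", "0", "1", "1", "3"],
                "dam": ["0", "0", "2", "2", "4"],
                "birth_year": [2000, 2000, 2001, 2001, 2002],
            }
        )
    )


@pytest.fixture
def small_random_pedigree(rng):
    return sb.pedigree_from_frame(random_pedigree_frame(60, rng))
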