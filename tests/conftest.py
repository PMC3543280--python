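import numpy as np
import pandas as pd
import pytest

from adiponet import PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_pheno(sample_ids, tg=None, bmi=None, age=None, sex=None,
               pair_id=None, group=None, rng=None) -> PhenotypeTable:
    n = len(sample_ids)
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame({
        "tg": tg if tg is not None else rng.uniform(0.5, 3.0, n),
        "bmi": bmi if bmi is not None else rng.uniform(20, 35, n),
        "age": age if age is not None else rng.uniform(25, 65, n),
        "sex": sex if sex is not None else rng.integers(0, 2, n),
        "pair_id": pair_id,
        "group": group,
    }, index=pd.Index(sample_ids, name="sample_id"))
    return PhenotypeTable(df)
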