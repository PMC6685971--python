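import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def manifest_csv(tmp_path):
    """A small, valid cohort manifest on disk."""

    def _write(rows):
        df = pd.DataFrame(rows)
        path = tmp_path / "manifest.csv"
        df.to_csv(path, index=False)
        return path

    return _write


def make_row(subject_id="S1", ahi=5.0, age=45.0, sex="male", bmi=30.0,
             nc=40.0, mps=2, **extra):
    row = dict(subject_id=subject_id, ahi=ahi, age=age, sex=sex, bmi=bmi,
               nc=nc, mps=mps, mouth_wav="", nose_wav="")
    row.update(extra)
    return row


@pytest.fixture
def two_group_table(rng):
    """Feature table with 3 informative + 17 null features, n = 30/20."""
    n_non, n_osa = 30, 20
    labels = pd.Series([False] * n_non + [True] * n_osa,
                       index=[f"s{i}" for i in range(n_non + n_osa)])
    cols = {}
    for j in range(3):
        base = rng.normal(size=n_non + n_osa)
        base[labels.to_numpy()] += 6.0
        cols[f"informative_{j}"] = base
    for j in range(17):
        cols[f"null_{j}"] = rng.normal(size=n_non + n_osa)
    df = pd.DataFrame(cols, index=labels.index)
    return df, labels
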