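import numpy as np
import pandas as pd
import pytest

import biogeo as bg


@pytest.fixture(scope="session")
def default_study():
    """One default reduced-scale study shared by read-only tests."""
    return bg.generate_study(bg.default_config(seed=42))


@pytest.fixture()
def tiny_table():
    return bg.CountTable(["t1", "t2"], ["s1", "s2"], np.array([[1, 2], [3, 4]]))


@pytest.fixture()
def tiny_meta():
    return bg.SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "subject_id": ["p1", "p1"],
                "organ": ["stomach", "stomach"],
                "site": ["antrum", "antrum"],
                "sample_type": ["mucosa", "gastric_juice"],
                "age": [60, 60],
            }
        )
    )


def make_meta(rows):
    """Helper: build a SampleTable from (sample, subject, organ, site, type) tuples."""
    return bg.SampleTable(
        pd.DataFrame(
            rows, columns=["sample_id", "subject_id", "organ", "site", "sample_type"]
        )
    )
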