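import numpy as np
import pandas as pd
import pytest

from stabilome.io_model import CountTable, SampleMetadata, read_newick


@pytest.fixture
def toy_tree():
    """The worked 3-tip tree: ((A:1,B:1):1,C:2); total branch length 5."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_counts():
    return CountTable(pd.DataFrame(
        {"s1": [1, 3], "s2": [2, 4]}, index=["f1", "f2"]
    ))


@pytest.fixture
def random_counts():
    rng = np.random.default_rng(42)
    data = rng.integers(0, 50, size=(50, 12))
    return CountTable(pd.DataFrame(
        data, index=[f"f{i}" for i in range(50)], columns=[f"s{j}" for j in range(12)]
    ))


@pytest.fixture
def design_metadata():
    rows = []
    for exp in (-1, -4, -7, -10):
        for ph in (4.5, 5.5, 6.5, 7.5, 8.5):
            for rep in (1, 2, 3, 4, 5, 6):
                rows.append({"sample": f"D{exp}_pH{ph:g}_r{rep}",
                             "dilution_exponent": exp, "pH": ph, "replicate": rep})
    return SampleMetadata(pd.DataFrame(rows).set_index("sample"))
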