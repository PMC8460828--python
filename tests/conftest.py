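import numpy as np
import pandas as pd
import pytest

from ninep21.io import ClinicalTable, CopyCallTable, ExpressionMatrix, GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr():
    """5 genes x 6 samples, fixed values (includes the 9p21 anchors)."""
    genes = ["CDKN2A", "MTAP", "G1", "G2", "G3"]
    samples = [f"S{i}" for i in range(6)]
    rng = np.random.default_rng(7)
    vals = rng.normal(5.0, 1.0, size=(5, 6)).round(3)
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))


@pytest.fixture
def copy_calls():
    """Four samples covering LOSS / LOH / WT / OTHER."""
    df = pd.DataFrame(
        {
            "A": [-2, -2, 0],
            "B": [-1, -1, -1],
            "C": [0, 0, 0],
            "D": [-1, 0, 1],
        },
        index=["CDKN2A", "MTAP", "IFNA1"],
    )
    return CopyCallTable(df)


@pytest.fixture
def clinical():
    df = pd.DataFrame(
        {
            "response": ["CR", "PR", "SD", "PD", "SD", "NE"],
            "os_time": [20.0, 15.0, 10.0, 4.0, 8.0, 12.0],
            "os_event": [False, True, True, True, False, False],
            "pfs_time": [18.0, 12.0, 7.0, 2.0, 4.0, 9.0],
            "pfs_event": [False, True, True, True, True, False],
            "tmb": [12.0, 30.0, 5.0, 2.0, np.nan, 8.0],
            "pdl1_ic": ["IC2+", "IC1", "IC0", "IC0", "IC2+", None],
        },
        index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
    )
    return ClinicalTable(df)


@pytest.fixture
def gene_sets():
    return GeneSetCollection(
        {"setA": ["G1", "G2"], "setB": ["G3"], "absent": ["NOPE1", "NOPE2"]},
        categories={"setA": "cell-type markers"},
    )
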