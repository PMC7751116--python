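import numpy as np
import pytest

import sbnet


@pytest.fixture
def toy_counts(tmp_path):
    """2x3 raw-count TSV on disk."""
    path = tmp_path / "counts.tsv"
    path.write_text(
        "sample_id\ttaxA\ttaxB\ttaxC\n"
        "s1\t2\t3\t5\n"
        "s2\t1\t0\t9\n"
    )
    return path


@pytest.fixture
def collider_dag():
    """X -> Z <- Y with unit weights."""
    return sbnet.TrueDAG(
        ["X", "Y", "Z"], {("X", "Z"): 1.0, ("Y", "Z"): 1.0}
    )


@pytest.fixture
def chain_dag():
    """X -> Y -> Z."""
    return sbnet.TrueDAG(
        ["X", "Y", "Z"], {("X", "Y"): 1.0, ("Y", "Z"): 1.0}
    )


@pytest.fixture
def collider_data(collider_dag):
    return sbnet.sample_linear_gaussian(collider_dag, 1000, seed=42)
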