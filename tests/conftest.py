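import numpy as np
import pytest

import bigsea as bg


@pytest.fixture
def small_expression():
    """3 genes x 4 samples with hand-chosen values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [5.5, 5.0, 4.5, 4.0],
            [2.0, 2.0, 2.0, 2.0],
        ]
    )
    return bg.ExpressionMatrix(values, ["gA", "gB", "gC"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def two_groups_4():
    return bg.SampleGroups(
        {"s1": "control", "s2": "control", "s3": "treated", "s4": "treated"}
    )


@pytest.fixture
def random_study():
    """Random 100-gene, 7 vs 7 study with planted up / bidirectional / null sets."""
    cfg = bg.SimConfig(
        n_genes=100,
        set_specs=[
            bg.SetSpec("up_set", 10, "up", 2.0),
            bg.SetSpec("bidir_set", 10, "bidirectional", 2.0),
            bg.SetSpec("null_set", 10, "null"),
        ],
        seed=11,
    )
    x, groups, sets, truth = bg.simulate_expression(cfg)
    return x, groups, sets, truth


def make_groups(n_a: int, n_b: int, labels=("A", "B")):
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    return ids, bg.SampleGroups(
        {s: (labels[0] if s.startswith("a") else labels[1]) for s in ids}
    )
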