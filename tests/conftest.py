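import numpy as np
import pytest

from starcoal import ExpansionModel, SimConfig, parse_newick


@pytest.fixture
def balanced4():
    """Balanced 4-tip tree, all six branches length 1 (total 6)."""
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar4():
    """Caterpillar (((A,B),C),D), all branches length 1."""
    return parse_newick("(((A:1,B:1):1,C:1):1,D:1);")


@pytest.fixture
def star3():
    """3-tip star with branch lengths 2, 3, 5."""
    return parse_newick("(A:2,B:3,C:5);")


@pytest.fixture
def constant_model():
    """Constant-size population of 1000 men."""
    return ExpansionModel(start_n=1000, end_n=1000, t_end_years=0, duration_years=0)


@pytest.fixture
def europe_model():
    return ExpansionModel(start_n=2, end_n=9500, t_end_years=12000, duration_years=325)


@pytest.fixture
def africa_model():
    return ExpansionModel(start_n=40, end_n=2000, t_end_years=2000, duration_years=12000)


def random_tree_newick(rng, n_tips=10):
    """Random rooted tree (random joins, exponential branch lengths)."""
    nodes = [f"t{i}:{rng.exponential(1.0) + 0.01:.6f}" for i in range(n_tips)]
    while len(nodes) > 1:
        k = 3 if (len(nodes) > 2 and rng.random() < 0.2) else 2
        picks = sorted(rng.choice(len(nodes), size=k, replace=False), reverse=True)
        children = [nodes.pop(i) for i in picks]
        if len(nodes) == 0:
            nodes.append("(" + ",".join(children) + ")")
        else:
            nodes.append(
                "(" + ",".join(children) + f"):{rng.exponential(1.0) + 0.01:.6f}"
            )
    return nodes[0] + ";"
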