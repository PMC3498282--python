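import numpy as np
import pytest

from divrate.simulate import TreeSimSpec, sample_yule_branching_ages, simulate_yule


@pytest.fixture
def cherry_plus_one():
    """The worked 3-tip tree ((A:1,B:1):1,C:2); with branching ages [2, 1]."""
    from divrate.tree import parse_tree

    return parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def bt_3():
    from divrate.tree import BranchingTimes

    return BranchingTimes(3, np.array([2.0, 1.0]))


def make_yule_bt(n_tips, lam, seed):
    rng = np.random.default_rng(seed)
    return sample_yule_branching_ages(n_tips, lam, rng)


def make_yule_tree(n_tips, lam, seed):
    return simulate_yule(TreeSimSpec("yule", n_tips, lam=lam, seed=seed))
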