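import numpy as np
import pytest

from quatfold import (
    ChromatinReconstructor,
    ConstraintSet,
    build_initial_chain,
    make_tad_fixture,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tad_fixture():
    """Default synthetic ground truth: 3 TADs x 8 bins, strong diagonal blocks."""
    return make_tad_fixture()


def random_chain(n_beads=10, seed=0, radius=60.0, **kwargs):
    """A feasible random finest-level chain under the default constraints."""
    cons = kwargs.pop("constraints", ConstraintSet())
    spec = [(radius, (i * 100_000, (i + 1) * 100_000)) for i in range(n_beads)]
    return build_initial_chain(spec, cons, np.random.default_rng(seed), **kwargs)


@pytest.fixture(scope="session")
def recovery_runs(tad_fixture):
    """Five independent seeded reconstructions of the default fixture.

    Session-scoped because each run performs the full multiscale anneal;
    shared by the recovery, constraint-guarantee and rigidity checks.
    """
    matrix, partition, truth = tad_fixture
    runs = []
    for seed in range(1, 6):
        est = ChromatinReconstructor(partition=list(partition.blocks), random_state=seed)
        est.fit(matrix)
        runs.append(est)
    return runs
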