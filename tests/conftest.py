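import numpy as np
import pytest

from standthin import (
    StandSnapshot,
    TreeRecord,
    default_factorial,
    default_growth_params,
    height_from_dbh,
    simulate_scenario,
)


def make_snapshot(dbhs, heights=None, *, plot_id="P1", age=10, area_ha=0.04, treatment="CK"):
    """Build a snapshot from raw DBH (and optional height) lists."""
    params = default_growth_params()
    trees = []
    for i, d in enumerate(dbhs, start=1):
        h = heights[i - 1] if heights is not None else float(height_from_dbh(d, params))
        trees.append(TreeRecord(i, float(d), float(h)))
    return StandSnapshot(plot_id, age, trees, area_ha=area_ha, treatment=treatment)


def random_snapshot(rng, n=None, **kwargs):
    n = n if n is not None else int(rng.integers(5, 60))
    dbhs = rng.lognormal(mean=np.log(12), sigma=0.3, size=n)
    heights = 1.3 + 1.1 * dbhs**0.85
    return make_snapshot(dbhs, heights, **kwargs)


@pytest.fixture(scope="session")
def factorial_trajectories():
    """The calibrated seven-treatment x three-replicate factorial, seed 1.

    Session-scoped: this is the single largest computation in the suite and
    several modules assert different properties of the same run.
    """
    config = default_factorial(replicates=3, base_seed=1)
    return simulate_scenario(config, default_growth_params())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
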