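import numpy as np
import pytest

import landcast as lc


@pytest.fixture(scope="session")
def fixture_small():
    """Hand-set 12×12 two-country world."""
    return lc.make_fixture_small()


@pytest.fixture(scope="session")
def small_run(fixture_small):
    """Full scenario run on the hand-set world, country scenario, seed 1."""
    world, table, crops = fixture_small
    cfg = lc.ScenarioConfig(scenario_name="fixture", seed=1,
                            irrigation_strictness=2.0)
    return lc.run_scenario(world, table, crops, cfg)


@pytest.fixture(scope="session")
def gen_world():
    """Seeded 60×60 synthetic world with 4 countries."""
    return lc.generate_world(lc.WorldParams(shape=(60, 60)), seed=7)


@pytest.fixture(scope="session")
def gen_run(gen_world):
    world, table, crops = gen_world
    cfg = lc.ScenarioConfig(scenario_name="synth", seed=3)
    return lc.run_scenario(world, table, crops, cfg)


def greedy_frontier_oracle(score, eligible, extent, n):
    """Independent single-cell greedy oracle for expansion allocation.

    Re-ranks the 8-neighbour frontier of the growing extent after every
    single-cell conversion; relaxes to any eligible cell when the
    frontier is empty (or when there is no seed extent at all).
    """
    ny, nx = score.shape
    occupied = {tuple(p) for p in np.argwhere(extent)}
    converted = set()

    def neighbours(p):
        r, c = p
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) != (0, 0) and 0 <= r + dr < ny and 0 <= c + dc < nx:
                    yield (r + dr, c + dc)

    for _ in range(n):
        cand = [p for p in map(tuple, np.argwhere(eligible))
                if p not in converted
                and any(q in occupied or q in converted for q in neighbours(p))]
        if not cand or not occupied:
            cand = [p for p in map(tuple, np.argwhere(eligible))
                    if p not in converted]
        pick = max(cand, key=lambda p: score[p])
        converted.add(pick)
    return converted
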