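import numpy as np
import pytest

from chemokit import MotilityConfig, SimulationParams, simulate_run_and_tumble


@pytest.fixture
def motility_config() -> MotilityConfig:
    return MotilityConfig()


@pytest.fixture
def turn_fixture():
    """Hand-built 90-degree-turn trajectory with a 2-frame speed dip.

    20 frames straight at speed v, two frames at v/2 heading 90 degrees off,
    then 20 frames straight along the new heading. Exactly one reorientation
    event (at the turn) satisfies both the 25-degree and the 70%-speed
    criteria; frame rate 30 Hz.
    """
    dt = 1.0 / 30.0
    v = 30.0  # um/s
    step = v * dt
    pts = [np.array([0.0, 0.0])]
    for _ in range(20):
        pts.append(pts[-1] + [step, 0.0])
    for _ in range(2):
        pts.append(pts[-1] + [0.0, 0.5 * step])
    for _ in range(20):
        pts.append(pts[-1] + [0.0, step])
    return np.array(pts), dt


@pytest.fixture(scope="session")
def small_simulation():
    """A modest run-and-tumble simulation shared across read-only tests."""
    params = SimulationParams(
        n_cells=40, duration=10.0, tumble_rate=0.5, turn_angle_min=45.0,
        nonmotile_fraction=0.0, noise_sd=0.05, seed=123,
    )
    return params, simulate_run_and_tumble(params)


def brute_force_assignment(prev_xy, new_xy, max_disp):
    """Exhaustive gated matching oracle: maximise the number of links whose
    displacement is within ``max_disp``, then minimise total squared cost.

    Enumerates every injective mapping from previous points to detections;
    independent of the production linker. Returns (n_links, total_cost).
    """
    from itertools import permutations

    n, m = len(prev_xy), len(new_xy)
    if n == 0 or m == 0:
        return 0, 0.0
    d2 = ((prev_xy[:, None, :] - new_xy[None, :, :]) ** 2).sum(axis=2)
    feasible = d2 <= max_disp ** 2
    best = (0, 0.0)
    idx = list(range(m)) + [-1] * max(n - m, 0)   # -1 = unmatched
    seen = set()
    for perm in permutations(idx, n):
        if perm in seen:
            continue
        seen.add(perm)
        links = 0
        cost = 0.0
        for i, j in enumerate(perm):
            if j >= 0 and feasible[i, j]:
                links += 1
                cost += d2[i, j]
        if links > best[0] or (links == best[0] and cost < best[1]):
            best = (links, cost)
    return best
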