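import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import meamask as mm

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

CENTER = (1837.5, 1050.0)  # acquired-region center, on an electrode center


@pytest.fixture(scope="session")
def grid() -> mm.ElectrodeGrid:
    return mm.build_grid()


@pytest.fixture(scope="session")
def design() -> mm.NetworkDesign:
    return mm.generate_network_design(center=CENTER)


@pytest.fixture(scope="session")
def rasterized(design, grid):
    """(expected CoverageMap, ElectrodeGroups) of one centered network."""
    cov, groups = mm.rasterize_design(
        mm.MicrostructureLayout([design]), grid)
    return cov, groups[0]


@pytest.fixture(scope="session")
def patches(grid):
    return mm.plan_patches(grid)


@pytest.fixture(scope="session")
def activity_recording(rasterized):
    """A short spontaneous-activity recording on a routed subset."""
    from meamask.pipeline import _routed_subset
    _, groups = rasterized
    params = mm.ActivitySimParams(duration_s=10.0, event_rate_hz=2.0,
                                  direction="clockwise", seed=42)
    routed = _routed_subset(groups, per_node=8)
    return mm.simulate_network_activity(groups, params,
                                        routed_electrodes=routed)


def match_spike_times(true_times: np.ndarray, detected_times: np.ndarray,
                      tol_s: float = 0.25e-3) -> tuple[float, float]:
    """(recall, precision) with one-to-one greedy matching at +/- tol."""
    true_times = np.sort(np.asarray(true_times))
    detected_times = np.sort(np.asarray(detected_times))
    used = np.zeros(detected_times.size, dtype=bool)
    hits = 0
    for t in true_times:
        cand = np.flatnonzero(~used
                              & (np.abs(detected_times - t) <= tol_s))
        if cand.size:
            used[cand[0]] = True
            hits += 1
    recall = hits / true_times.size if true_times.size else 1.0
    precision = hits / detected_times.size if detected_times.size else 1.0
    return recall, precision
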