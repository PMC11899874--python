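import numpy as np
import pytest

import precimap as pm


@pytest.fixture(scope="session")
def grid100():
    """10x10 grid mesh, 1 mm spacing."""
    return pm.build_toy_surface(100, "grid")


@pytest.fixture(scope="session")
def path5():
    """5-node path graph (1x5 degenerate grid), unit edge lengths."""
    return pm.build_toy_surface(5, "grid")


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects, 100 grayordinates, 4 networks, 5 minutes each."""
    cfg = pm.SimulationConfig(
        n_subjects=3,
        n_grayordinates=100,
        n_networks=4,
        duration_minutes=5.0,
        within_network_signal_fraction=0.9,
        boundary_jitter=0.2,
        rng_seed=7,
    )
    return pm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_templates(tiny_cohort):
    """Template set built from the tiny cohort (smoothed + censored)."""
    weights = pm.gaussian_smoothing_weights(tiny_cohort.mesh, 2.25)
    per_subject, processed = [], []
    for sub in tiny_cohort.subjects:
        series = pm.smooth_series(sub.series, tiny_cohort.mesh, 2.25, weights=weights)
        series = pm.censor_frames(series, sub.fd, 0.3)
        processed.append(series)
        per_subject.append(pm.subject_seed_maps(series, tiny_cohort.group_truth))
    tset = pm.average_and_threshold(per_subject, tiny_cohort.group_truth.table)
    return tset, processed


def random_series(n_frames: int, n_grayordinates: int, seed: int = 0, tr: float = 0.8):
    rng = np.random.default_rng(seed)
    return pm.GrayordinateSeries(
        rng.standard_normal((n_frames, n_grayordinates)), tr
    )
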