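import numpy as np
import pytest

import lifelog_rsa as lr


@pytest.fixture(scope="session")
def vocab():
    return lr.load_vocabulary()


@pytest.fixture(scope="session")
def small_study():
    """A compact study with an embedded signal region, shared across tests."""
    cfg = lr.GeneratorConfig(
        seed=202,
        n_participants=4,
        n_events=36,
        grid_shape=(8, 8, 8),
        signal_center=(4, 4, 4),
    )
    return lr.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_pairs(small_study):
    return lr.build_study_pairs(small_study)


@pytest.fixture(scope="session")
def region_fits(small_study, small_pairs):
    """Per-subject full-model fits on the pooled true signal region."""
    from lifelog_rsa.pair_builder import neural_distances
    from lifelog_rsa.searchlight_rsa import fit_pair_glm

    gt = small_study.ground_truth
    fits = {}
    for pid in small_study.events:
        nd = neural_distances(
            small_study.betas[pid], gt.signal_voxels, small_pairs[pid]
        )
        fits[pid] = fit_pair_glm(nd, small_pairs[pid], lr.VIVIDNESS_MODEL)
    return fits


def make_event(
    pid="p1",
    event_id="e0",
    clock_time=0.0,
    lat=40.0,
    lon=-83.0,
    tags=(1, 0, 1),
    remembered=True,
    vivid=True,
    scanner_onset=0.0,
    usable=True,
):
    return lr.EventRecord(
        event_id=event_id,
        participant_id=pid,
        clock_time=clock_time,
        lat=lat,
        lon=lon,
        tagvec=np.asarray(tags, dtype=np.uint8),
        remembered=remembered,
        vivid=vivid if remembered else None,
        scanner_onset=scanner_onset,
        usable=usable,
    )
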