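import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

DESK_SCALE = 0.25


@pytest.fixture(scope="session")
def desk_stats():
    """Counting thresholds at the 0.25 desk geometry scale."""
    from pigtrack.correction import CountingStats
    return CountingStats().scaled(DESK_SCALE)


@pytest.fixture(scope="session")
def trained_reid():
    """A desk-scale re-ID network trained once on 10 rendered identities.

    Shared by the embedding-quality tests and the training acceptance
    check; returns (extractor, history, crops, labels, spec).
    """
    from pigtrack.reid import ReIDSpec, build_reid, train_reid
    from pigtrack.sim import render_crops

    crops, labels = render_crops(n_ids=10, per_id=30, hw=(32, 64), seed=42)
    spec = ReIDSpec(input_hw=(32, 64), width_mult=0.25)
    extractor = build_reid(spec, seed=0)
    extractor, history = train_reid(extractor, crops, labels, epochs=12, seed=0)
    return extractor, history, crops, labels, spec


def clean_scenario_count(seed: int, n_pigs: int, **kwargs):
    """Run the full pipeline on a clean seeded scenario; returns the result."""
    from pigtrack.correction import CountingStats
    from pigtrack.counting import compute_stats, count_stream
    from pigtrack.sim import DetectionNoise, SimParams, generate_scenario, oracle_detections
    from pigtrack.tracker import TrackerConfig

    params = SimParams(n_pigs=n_pigs, scale=DESK_SCALE, **kwargs)
    gt = generate_scenario(params, seed)
    dets = oracle_detections(gt, DetectionNoise(), seed)
    stats = compute_stats(gt.tracks())
    return gt, count_stream(dets, TrackerConfig(), stats, frame_width=gt.frame_width)
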