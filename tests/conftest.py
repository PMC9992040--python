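import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from perfopulse import analyze_scan, detect_perforators
from perfopulse.synthetic_cine import match_detections, render_cine, standard_scene

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

SCENE_SEED = 2024  # fixed seed of the benchmark detection scene


@pytest.fixture(scope="session")
def standard_scene_run():
    """Render + detect + analyze the benchmark scene once per session.

    50 circular perforators (vPI 0.45), 10 oblique decoys (axis ratio 3),
    10 ghost decoys, tissue SNR 10.
    """
    perfs, ghosts, acq = standard_scene(seed=SCENE_SEED)
    series, roi, truth = render_cine(perfs, acq, ghosts=ghosts)
    vessels = detect_perforators(series, roi)
    match = match_detections(vessels, truth)
    stats = analyze_scan(series, vessels)
    return {
        "series": series,
        "roi": roi,
        "truth": truth,
        "vessels": vessels,
        "match": match,
        "stats": stats,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
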