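import numpy as np
import pytest

from scalphfo.detect import DetectorConfig, apply_average_montage, bandpass_ripple
from scalphfo.synth import generate_feature_table, make_detection_scene, paper_mixture

FS = 1024.0


@pytest.fixture(scope="session")
def paper_table():
    """One seeded draw of the published-centroid feature fixture."""
    return generate_feature_table(paper_mixture(seed=0))


@pytest.fixture(scope="session")
def small_scene():
    """A compact single-burst scene plus its band-passed form (reused
    across detector tests)."""
    rec, truth, spikes, scene = make_detection_scene(
        0, duration=20.0, n_bursts=1, snr_range=(8.0, 8.0),
        n_subthreshold=0, spike_fraction=0.0,
    )
    filt = bandpass_ripple(apply_average_montage(rec))
    return rec, filt, truth


@pytest.fixture()
def config():
    return DetectorConfig()
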