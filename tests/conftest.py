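import pytest
from hypothesis import HealthCheck, settings

from chipcal.simulate import (
    SimConfig, make_annotation, make_replicate_peaks, make_truth_sites,
    make_tracks, plant_element,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cfg0():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def sim0(cfg0):
    """One fully simulated dataset at seed 0, shared across tests."""
    annotation = make_annotation(cfg0)
    element = plant_element(cfg0, annotation)
    truth = make_truth_sites(cfg0, annotation)
    reps = make_replicate_peaks(cfg0, truth)
    marks, conservation, binding = make_tracks(cfg0, annotation, truth, element)
    return {
        "cfg": cfg0, "annotation": annotation, "element": element,
        "truth": truth, "reps": reps, "marks": marks,
        "conservation": conservation, "binding": binding,
    }
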