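import numpy as np
import pytest

from thermomix import Dataset, DevelopmentRecord, preset_model
from thermomix.synthetic import ComponentDesign, SimulationDesign, sample_dataset

# Six published example rows from the C. maxillosus rearing experiment.
EXAMPLE_ROWS = [
    (109.79, 15.0),
    (141.13, 15.0),
    (66.25, 15.0),
    (87.12, 17.5),
    (62.08, 17.5),
    (70.29, 17.5),
]


@pytest.fixture
def example_csv(tmp_path):
    path = tmp_path / "creophilus_sample.csv"
    lines = ["dev_time_days,temp_C"] + [f"{d},{t}" for d, t in EXAMPLE_ROWS]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def necrodes_model():
    """Published two-component fit for N. littoralis."""
    return preset_model("necrodes_littoralis")


@pytest.fixture
def creophilus_model():
    """Published two-component fit for C. maxillosus."""
    return preset_model("creophilus_maxillosus")


@pytest.fixture
def exact_law_data():
    """Three noise-free points on 1/D = (T - 10)/400, i.e. k=400, t0=10."""
    points = [(15.0, 400.0 / 5), (20.0, 400.0 / 10), (25.0, 400.0 / 15)]
    return Dataset([DevelopmentRecord(d, t) for t, d in points])


def single_component_design(n: int, seed: int, shape=14.0, scale=400.0, t0=10.0):
    return SimulationDesign(
        components=(ComponentDesign(1.0, shape, scale, t0),),
        temperatures=(15.0, 20.0, 25.0),
        n=n,
        seed=seed,
    )


@pytest.fixture
def single_component_data():
    return sample_dataset(single_component_design(n=1000, seed=11))
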