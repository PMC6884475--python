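import numpy as np
import pytest

from lanecue.course import RoadCourse, Segment, generate_course


@pytest.fixture(scope="session")
def course():
    """A default-parameter random course used across tests."""
    return generate_course(12345)


@pytest.fixture(scope="session")
def toy_course():
    """Hand-built straight/arc/straight/arc/straight course (known geometry)."""
    segs = [
        Segment("straight", 100.0, 0.0, 0.0),
        Segment("arc", 100.0, 0.01, 100.0),
        Segment("straight", 100.0, 0.0, 200.0),
        Segment("arc", 100.0, -0.008, 300.0),
        Segment("straight", 100.0, 0.0, 400.0),
    ]
    return RoadCourse(segs)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
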