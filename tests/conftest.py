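import numpy as np
import pytest

from oxypond.io import SampleSet
from oxypond.synth import default_field_spec, sample_sensors


@pytest.fixture
def two_groups():
    """Two tight clusters of 5 points each in normalized 4-space.

    Spread << separation, so density-based seeding must find exactly one
    center per group; true group means are returned for oracle checks.
    """
    rng = np.random.default_rng(7)
    mean_a = np.array([0.2, 0.2, 0.2, 0.2])
    mean_b = np.array([0.8, 0.8, 0.8, 0.8])
    a = mean_a + rng.normal(0, 0.01, (5, 4))
    b = mean_b + rng.normal(0, 0.01, (5, 4))
    return np.vstack([a, b]), np.vstack([a.mean(0), b.mean(0)])


@pytest.fixture
def rectangle_points():
    """Four corners of a long rectangle in the first two coordinates.

    With 2 clusters the SSE optimum puts centers at the short-side
    midpoints.
    """
    pts = np.array([
        [0.0, 0.0, 0.0, 0.0],
        [0.0, 1.0, 0.0, 0.0],
        [10.0, 0.0, 0.0, 0.0],
        [10.0, 1.0, 0.0, 0.0],
    ])
    optimum = np.array([[0.0, 0.5, 0.0, 0.0], [10.0, 0.5, 0.0, 0.0]])
    return pts, optimum


@pytest.fixture
def pond_survey():
    """A 100-sample synthetic survey of the stock pond (seed 0)."""
    return sample_sensors(default_field_spec(seed=0), layout="random", n=100)


@pytest.fixture
def small_survey():
    """A small noiseless survey for fast exact checks."""
    spec = default_field_spec(seed=3, noise_sd=0.0)
    return sample_sensors(spec, layout="random", n=24)


@pytest.fixture
def sample_csv(tmp_path):
    """Write a survey-schema CSV with clock times and return its path."""
    path = tmp_path / "samples.csv"
    path.write_text(
        "Time,X (m),Y (m),Z (m),Dissolved oxygen (mg/L)\n"
        "7:07,15,25,0.4,2.22\n"
        "7:07,15,25,1,1.95\n"
        "7:07,15,25,1.6,1.7\n"
        "7:10,22.5,25,0.4,2.26\n"
    )
    return path


def make_sampleset(X, y):
    X = np.asarray(X, dtype=float)
    return SampleSet.from_arrays(X[:, 0], X[:, 1], X[:, 2], X[:, 3], y)
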