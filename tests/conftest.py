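import numpy as np
import pytest

from dmdlv import ModelParams, SimulationConfig, peak_strain_params, simulate_cohort
from dmdlv.strain import SEGMENTS, StrainTimeCourse

#: posterior-mean peak-strain trajectory used as generating truth throughout
PEAK_ALPHA = np.array([-17.9, -17.0, -16.7, -17.0, -16.0, -14.9])


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_panel():
    """Tiny complete DMD panel (5 subjects x 4 visits) for likelihood tests."""
    cfg = SimulationConfig(params=peak_strain_params(beta=0.4, sigma_y=2.0),
                           n_subjects=5, n_visits=4, loa_mode="iid", seed=42)
    return simulate_cohort(cfg)


def make_timecourse(values, segments=None):
    return StrainTimeCourse(segments=list(segments or SEGMENTS),
                            values=np.asarray(values, dtype=float))


def first_harmonic_timecourse(n_frames=12, amplitude=1.0):
    """Zero-mean pure first spatial harmonic, scaled over time."""
    k = np.arange(6)
    spatial = np.cos(2.0 * np.pi * k / 6)
    temporal = -amplitude * np.sin(np.pi * np.arange(n_frames) / n_frames)
    return make_timecourse(np.outer(spatial, temporal))
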