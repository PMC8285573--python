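import numpy as np
import pytest

from lvloops.geometry import compute_geometry_series
from lvloops.loops import decompose_stroke_work
from lvloops.phantom import (
    PhantomParams,
    PhantomPressure,
    generate_phantom,
    frame_pressure_curve,
    patient_like_params,
    thin_wall_params,
)


class PhantomRun:
    """A phantom pushed through the full analysis pipeline."""

    def __init__(self, params: PhantomParams, n: int = 100):
        self.params = params
        self.data = generate_phantom(params)
        self.geometry = compute_geometry_series(self.data.contours, self.data.tracks, n=n)
        self.pressure = frame_pressure_curve(self.data, n)
        self.decomposition = decompose_stroke_work(self.geometry, self.pressure)

    @property
    def truth(self):
        return self.data.truth


@pytest.fixture(scope="session")
def default_run() -> PhantomRun:
    """Mid-size phantom, physiological 10 mm wall, mixed motion."""
    return PhantomRun(PhantomParams())


@pytest.fixture(scope="session")
def thin_mixed_run() -> PhantomRun:
    """Membrane-limit wall, mixed longitudinal + radial motion."""
    return PhantomRun(thin_wall_params())


@pytest.fixture(scope="session")
def pure_long_run() -> PhantomRun:
    """Longitudinal motion only (no epicardial inward excursion)."""
    return PhantomRun(PhantomParams(epi_inward_amplitude=0.0))


@pytest.fixture(scope="session")
def pure_rad_run() -> PhantomRun:
    """Radial motion only, membrane-limit wall."""
    return PhantomRun(thin_wall_params(avpd_amplitude=0.0))


@pytest.fixture(scope="session")
def rect_run() -> PhantomRun:
    """Rectangular pressure waveform, densely sampled frames, so PV
    stroke work has a closed form (eject - fill) * SV."""
    return PhantomRun(
        PhantomParams(
            n_frames=100,
            pressure=PhantomPressure(
                waveform="rectangular", eject_level=90.0, fill_level=10.0
            ),
        )
    )


@pytest.fixture(scope="session")
def patient_run() -> PhantomRun:
    """Dilated heart-failure-like ventricle (EDV ~350 mL, EF ~26%)."""
    return PhantomRun(patient_like_params())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
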