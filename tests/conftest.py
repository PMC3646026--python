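import numpy as np
import pytest

from dicomcbir import PhantomObject, PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def square_phantom():
    """Noise-free 64x64 phantom with one 10x10 bright square."""
    spec = PhantomSpec(
        shape=(64, 64),
        background_level=0.2,
        objects=[PhantomObject("rectangle", 0.8,
                               dict(row0=10, row1=19, col0=20, col1=29))],
        seed=1,
    )
    return make_phantom(spec)


@pytest.fixture
def mammo_phantom():
    """Noise-free breast-like disc with 5 injected speckles."""
    center, radius = (64, 64), 45
    spec = PhantomSpec(
        shape=(128, 128),
        background_level=0.05,
        objects=[PhantomObject("disc", 0.5, dict(center=center, radius=radius))],
        speckle_count=5,
        speckle_radius_px=2,
        speckle_level=0.9,
        speckle_region=(center, radius),
        modality="MG",
        uid="1.2.3.4.5",
        seed=11,
    )
    return make_phantom(spec)
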