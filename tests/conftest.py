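import numpy as np
import pytest

import cordseg as cs


@pytest.fixture(scope="session")
def clean_straight_phantom() -> cs.PhantomInstance:
    """Noise-free straight cord, 4 mm radius, 0.3 mm grid, 30 slices."""
    return cs.generate_phantom(cs.PhantomSpec(n_slices=30, seed=0))


@pytest.fixture(scope="session")
def clean_curved_phantom() -> cs.PhantomInstance:
    """Noise-free curved cord (5 mm sinusoidal amplitude), 200 slices."""
    return cs.generate_phantom(
        cs.PhantomSpec(n_slices=200, curve_amplitude_mm=5.0, seed=3)
    )


@pytest.fixture(scope="session")
def realistic_phantom() -> cs.PhantomInstance:
    """Curved cord with edge blur, 0.8-1.2x bias field and Rician noise at
    SNR 15 — the degradations of a real T2 acquisition."""
    return cs.generate_phantom(
        cs.PhantomSpec(
            n_slices=210,
            curve_amplitude_mm=5.0,
            edge_blur_mm=0.3,
            noise_snr=15.0,
            bias_range=(0.8, 1.2),
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def realistic_chain(realistic_phantom):
    """Full segmentation chain (S1-S7) on the realistic phantom."""
    slices = cs.segment_volume(realistic_phantom.volume)
    cord = cs.correct_segmentation(slices, realistic_phantom.spec.spacing)
    return slices, cord


@pytest.fixture(scope="session")
def curved_chain(clean_curved_phantom):
    slices = cs.segment_volume(clean_curved_phantom.volume)
    cord = cs.correct_segmentation(slices, clean_curved_phantom.spec.spacing)
    return slices, cord


def disk_mask(shape, center, radius):
    ii, jj = np.mgrid[: shape[0], : shape[1]]
    return (ii - center[0]) ** 2 + (jj - center[1]) ** 2 <= radius**2
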