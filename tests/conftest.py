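import numpy as np
import pytest

from mrvs import MrvsSegmenter, PhantomSpec, generate_phantom

MM_PER_PX = 3.0 / 320


@pytest.fixture(scope="session")
def low_noise_bundle():
    """Reference phantom: seed 42, near-deterministic speckle (shape 50)."""
    return generate_phantom(PhantomSpec(seed=42, speckle_shape=50.0))


@pytest.fixture(scope="session")
def segmented(low_noise_bundle):
    return MrvsSegmenter().fit(low_noise_bundle.image)


@pytest.fixture(scope="session")
def recovery_battery():
    """Fused-mask DSC and density errors on ten low-noise phantoms.

    Shared across the phantom-recovery and noise-degradation acceptance
    checks (the speckle-50 column is the common anchor).
    """
    out = {}
    for shape in (50.0, 8.0, 2.0):
        rows = []
        for seed in range(1, 11):
            bundle = generate_phantom(PhantomSpec(seed=seed, speckle_shape=shape))
            seg = MrvsSegmenter().fit(bundle.image)
            rows.append((bundle, seg))
        out[shape] = rows
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
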