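import numpy as np
import pytest

import pmri


@pytest.fixture(scope="session")
def harmonic_k4():
    """Noise-free 4-coil spatial-harmonic k-space, 128x128 speckle phantom.

    With L >= R harmonic coils every missing line is an exact linear
    combination of acquired coil lines, so GRAPPA-type reconstructions of
    this object must be exact to numerical precision.
    """
    img = pmri.make_phantom(128, 128, "speckle", seed=2)
    sens = pmri.make_sensitivities(4, 128, 128, "harmonic")
    return pmri.simulate_kspace(img, sens, noise_sigma=0.0)


@pytest.fixture(scope="session")
def harmonic_k8():
    """Noise-free 8-coil harmonic fixture (supports band ORFs up to 6)."""
    img = pmri.make_phantom(128, 128, "speckle", seed=2)
    sens = pmri.make_sensitivities(8, 128, 128, "harmonic")
    return pmri.simulate_kspace(img, sens, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_runs_128():
    """Ten seeded noisy 8-coil acquisitions of the smooth blob phantom at
    128x128 (sensitivities and noise vary per seed), with their SoS
    references; shared by the stochastic scheme-comparison tests."""
    img = pmri.make_phantom(128, 128, "blobs", seed=0)
    runs = []
    for seed in range(10):
        sens = pmri.make_sensitivities(8, 128, 128, "smooth-gaussian", seed=seed)
        full = pmri.simulate_kspace(img, sens, noise_sigma=0.02, seed=seed)
        ref = pmri.sos_combine(pmri.coil_images(full))
        runs.append((full, ref))
    return runs


def mean_ap(mask, runs, reconstruct=pmri.grappa_reconstruct, **kw):
    vals = []
    for full, ref in runs:
        rec = reconstruct(pmri.apply_mask(full, mask), mask, **kw)
        sos = pmri.sos_combine(pmri.coil_images(rec))
        vals.append(pmri.artifact_power(sos, ref))
    return float(np.mean(vals))
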