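import numpy as np
import pytest

from stillframe import (
    Beam,
    UnitCell,
    perturb_model,
    psi_beam,
    psi_detector,
    psi_envelope,
    simulate_still,
)

PSI_SEED = 424242


@pytest.fixture(scope="session")
def beam():
    return psi_beam()


@pytest.fixture(scope="session")
def detector():
    return psi_detector()


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free photosystem-I still shared across tests (read-only)."""
    return simulate_still(seed=PSI_SEED, noise_sigma_mm=0.0)


@pytest.fixture(scope="session")
def noisy_scene():
    """Quarter-pixel centroid noise, the default recovery condition."""
    return simulate_still(seed=PSI_SEED, noise_sigma_mm=0.03)


def random_q_inside_limiting_sphere(rng: np.random.Generator, beam: Beam, n: int):
    """Uniform random reciprocal points strictly inside the limiting sphere,
    excluding near-degenerate (origin / beam-collinear) configurations."""
    out = []
    while len(out) < n:
        q = rng.uniform(-2.0 * beam.k, 2.0 * beam.k, size=3)
        qn = np.linalg.norm(q)
        if not 1e-3 * beam.k < qn < 1.98 * beam.k:
            continue
        perp = np.linalg.norm(np.cross(q, beam.s0_hat))
        if perp < 1e-3 * qn:
            continue
        out.append(q)
    return np.array(out)
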