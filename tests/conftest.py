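import numpy as np
import pytest

from braingmm import phantom, pipeline

# the declared 3-component test mixture used for parameter-recovery checks
RECOVERY_MIXTURE = [(0.2, 60.0, 8.0), (0.3, 120.0, 10.0), (0.5, 200.0, 12.0)]


def sample_mixture(rng: np.random.Generator, components, n: int) -> np.ndarray:
    """Independent mixture sampler (test-side, separate from the package's)."""
    w = np.array([c[0] for c in components])
    idx = rng.choice(len(components), size=n, p=w / w.sum())
    mu = np.array([c[1] for c in components])[idx]
    sd = np.array([c[2] for c in components])[idx]
    return rng.normal(mu, sd)


def mixture_cdf(components):
    """Closed-form mixture CDF for KS tests (independent of package code)."""
    from scipy.stats import norm

    def cdf(x):
        x = np.asarray(x, dtype=float)
        total = np.zeros_like(x)
        for w, mu, sd in components:
            total += w * norm.cdf(x, mu, sd)
        return total

    return cdf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_truth():
    """One default phantom slice with ground truth."""
    return phantom.generate_phantom(phantom.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def default_cfg():
    return pipeline.RunConfig()


@pytest.fixture(scope="session")
def segmented(default_truth, default_cfg):
    """Full segmentation chain applied to the default phantom."""
    return pipeline.segment_image(default_truth.image, default_cfg)


@pytest.fixture(scope="session")
def recovery_samples():
    """50k seeded draws from the declared recovery mixture."""
    rng = np.random.default_rng(2024)
    return sample_mixture(rng, RECOVERY_MIXTURE, 50_000)
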