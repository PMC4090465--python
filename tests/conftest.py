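import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from shiftmotif.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Noisy 4-class dataset, 30 segments/class, with assignment gaps."""
    spec = SyntheticSpec(
        counts={c: 30 for c in ("HH", "EH", "HE", "EE")},
        residue_noise_sd=0.4,
        missing_rate=0.1,
        seed=101,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free, gap-free dataset: averaged features equal the latent draws."""
    spec = SyntheticSpec(
        counts={c: 20 for c in ("HH", "EH", "HE", "EE")},
        residue_noise_sd=0.0,
        missing_rate=0.0,
        seed=202,
    )
    return generate_dataset(spec)


def random_gaussian_problem(rng, n_classes=4, dim=None, n_per_class=None):
    """A random labelled Gaussian mixture for oracle-agreement tests."""
    from shiftmotif.defs import CLASSES

    dim = dim or int(rng.integers(2, 7))
    labels = CLASSES[:n_classes]
    X, y = [], []
    for lab in labels:
        n = n_per_class or int(rng.integers(15, 61))
        mean = rng.normal(0, 3, size=dim)
        A = rng.normal(0, 1, size=(dim, dim))
        cov = A @ A.T + 0.5 * np.eye(dim)
        X.append(rng.multivariate_normal(mean, cov, size=n))
        y += [lab] * n
    return np.vstack(X), y
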