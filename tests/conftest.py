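import numpy as np
import pytest

from grasprsa import RDM, build_default_design, model_rdm
from grasprsa.design import FACTORS


@pytest.fixture(scope="session")
def design():
    return build_default_design()


@pytest.fixture(scope="session")
def model_rdms(design):
    """Factor model RDMs converted to plain float RDMs."""
    out = {}
    for factor in FACTORS:
        m = model_rdm(design, factor)
        out[factor] = RDM(labels=m.labels, matrix=m.matrix.astype(float))
    return out


def random_rdm(rng, n=9, labels=None):
    """A valid random correlation-distance-like RDM for tests."""
    v = rng.uniform(0.05, 1.95, size=n * (n - 1) // 2)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = v
    m = m + m.T
    if labels is None:
        labels = tuple(f"C{i + 1}" for i in range(n))
    return RDM(labels=tuple(labels), matrix=m)


def pearson_sum_formula(x, y):
    """Definitional Pearson correlation by the raw sum formula (oracle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(
        (n * np.sum(x * x) - np.sum(x) ** 2) * (n * np.sum(y * y) - np.sum(y) ** 2)
    )
    return num / den
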