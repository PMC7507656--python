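import numpy as np
import pytest

from monopaf.simulation import MODEL_A, generate_dataset


@pytest.fixture
def cohort_a():
    """A medium cohort from mechanism A: (y, z, x, v) arrays."""
    df = generate_dataset(MODEL_A, 300, seed=20240917)
    return tuple(df[c].to_numpy() for c in ("y", "z", "x", "v"))


@pytest.fixture
def steep_cohort():
    """Data from a steeply increasing logistic truth in z.

    With a coarse basis and a large sample the monotone constraints are
    inactive at the optimum with overwhelming probability, so constrained and
    unconstrained fits should coincide.
    """
    rng = np.random.default_rng(0)
    n = 4000
    z = rng.uniform(size=n)
    z[np.argmin(z)] = 0.0
    x = rng.uniform(size=n)
    x[np.argmin(x)] = 0.0
    eta = -2.5 + 5.0 * z + 0.5 * x
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return y, z, x
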