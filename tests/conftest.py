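import numpy as np
import pytest

from smoothsum import LassosumProblem


def make_problem(rng, p=8, m=30, s=0.5, lam=0.125, yty=None):
    """A random Lassosum problem with a standardized reference matrix."""
    X = rng.standard_normal((m, p))
    X = X - X.mean(axis=0)
    X = X / np.linalg.norm(X, axis=0)
    y = rng.standard_normal(m)
    y = (y - y.mean()) / np.linalg.norm(y - y.mean())
    r = X.T @ y
    return LassosumProblem(
        ld_source=X, r=r, yty=float(y @ y) if yty is None else yty, s=s, lam=lam
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
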