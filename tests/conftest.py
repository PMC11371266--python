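import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def inner(a, b):
    return float(np.real(np.vdot(np.asarray(a), np.asarray(b))))


def assert_adjoint_pair(apply_fn, adjoint_fn, x_shape, y_shape, rng,
                        n_probes=20, rtol=1e-10, complex_range=False):
    """<A x, y> == <x, A^T y> on random probes."""
    for _ in range(n_probes):
        x = rng.standard_normal(x_shape)
        y = rng.standard_normal(y_shape)
        if complex_range:
            y = y + 1j * rng.standard_normal(y_shape)
        lhs = inner(apply_fn(x), y)
        rhs = inner(x, adjoint_fn(y))
        scale = max(abs(lhs), abs(rhs), 1e-30)
        assert abs(lhs - rhs) <= rtol * scale
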