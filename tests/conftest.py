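import numpy as np
import pytest

from actoflow import ModelParams, generate_mikado


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def reference_params():
    """Table-of-reference parameter set (50 x 20 um domain)."""
    return ModelParams()


@pytest.fixture
def small_params():
    """A small, fast network configuration used across unit tests."""
    return ModelParams(D_x=12.0, D_y=12.0, L=4.0, l_c=1.0, phi=0.5, seed=7)


@pytest.fixture
def small_network(small_params, rng):
    return generate_mikado(small_params, rng=rng)


def brute_force_overlaps(state):
    """Independent all-pairs segment-intersection oracle (minimum image)."""
    hits = []
    n = state.n
    prm = state.params
    shifts_x = [-prm.D_x, 0.0, prm.D_x] if state.periodic_x else [0.0]
    shifts_y = [-prm.D_y, 0.0, prm.D_y] if state.periodic_y else [0.0]
    for i in range(n):
        p1, b1 = state.p[i], state.b[i]
        d1 = b1 - p1
        for j in range(i + 1, n):
            found = None
            for sx in shifts_x:
                for sy in shifts_y:
                    p2 = state.p[j] + (sx, sy)
                    b2 = state.b[j] + (sx, sy)
                    d2 = b2 - p2
                    den = d1[0] * d2[1] - d1[1] * d2[0]
                    if abs(den) < 1e-12:
                        continue
                    r = p2 - p1
                    t = (r[0] * d2[1] - r[1] * d2[0]) / den
                    u = (r[0] * d1[1] - r[1] * d1[0]) / den
                    if 0 <= t <= 1 and 0 <= u <= 1:
                        found = (t, u)
            if found is not None:
                hits.append((i, j, found[0], found[1]))
    return hits
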