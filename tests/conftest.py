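import numpy as np
import pytest

from mbada import FixtureSpec, IntensityImage, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20221013)


@pytest.fixture
def nuclei_pair():
    """One 64x64 nuclei-like image with its ground-truth mask."""
    return generate(FixtureSpec(kind="nuclei_like", height=64, width=64, seed=7))


@pytest.fixture
def smooth_image():
    return generate(FixtureSpec(kind="random_smooth", height=48, width=48, seed=11))


def random_image(rng, h, w, channels=1) -> IntensityImage:
    shape = (h, w) if channels == 1 else (h, w, channels)
    return IntensityImage(rng.random(shape))


def brute_force_moments(pixels: np.ndarray, K: int, L: int) -> np.ndarray:
    """Moments by explicit double sums over the closed-form polynomials.

    Entirely independent of the matrix-product implementation: values
    come from exact integer arithmetic, norms from direct summation.
    """
    from mbada import scaled_polynomial_value

    N, M = pixels.shape
    tr = np.array([[scaled_polynomial_value(p, x, N) for x in range(N)]
                   for p in range(K + 1)])
    tc = np.array([[scaled_polynomial_value(q, y, M) for y in range(M)]
                   for q in range(L + 1)])
    rho_r = (tr**2).sum(axis=1)
    rho_c = (tc**2).sum(axis=1)
    out = np.empty((K + 1, L + 1))
    for p in range(K + 1):
        for q in range(L + 1):
            acc = 0.0
            for x in range(N):
                for y in range(M):
                    acc += tr[p, x] * tc[q, y] * pixels[x, y]
            out[p, q] = acc / (rho_r[p] * rho_c[q])
    return out
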