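import numpy as np
import pytest

from histoflux import SyntheticSpec, generate_section


@pytest.fixture(scope="session")
def clean_section():
    """Noise-free default synthetic section with ground truth."""
    return generate_section(SyntheticSpec(rng_seed=7))


@pytest.fixture(scope="session")
def noisy_section():
    """Same layout with noise at 10% of the vessel intensity."""
    spec = SyntheticSpec(rng_seed=7, noise_sd=300.0)
    return generate_section(spec)


def disk_mask(radius: int, pad: int = 6) -> np.ndarray:
    n = 2 * radius + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n]
    return (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= radius**2


def square_mask(side: int, pad: int = 6) -> np.ndarray:
    n = side + 2 * pad
    m = np.zeros((n, n), dtype=bool)
    m[pad:pad + side, pad:pad + side] = True
    return m


def koch_prefractal(iterations: int = 4, scale: float = 729.0,
                    pts_per_seg: int = 8) -> np.ndarray:
    """Dense point sampling of a Koch-curve prefractal (dimension log4/log3)."""
    p = np.array([[0.0, 0.0], [1.0, 0.0]])
    ang = -np.pi / 3
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    for _ in range(iterations):
        new = []
        for a, b in zip(p[:-1], p[1:]):
            d = b - a
            pa, pb = a + d / 3, a + 2 * d / 3
            new += [a, pa, pa + rot @ (d / 3), pb]
        new.append(p[-1])
        p = np.array(new)
    dense = []
    for a, b in zip(p[:-1], p[1:]):
        for t in np.linspace(0, 1, pts_per_seg, endpoint=False):
            dense.append(a + t * (b - a))
    dense.append(p[-1])
    return np.array(dense) * scale


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
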