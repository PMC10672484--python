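import math

import numpy as np
import pytest

from pelvikit import LandmarkSet, generate_cases


def three_values(mean: float, std: float, median: float) -> list[float]:
    """Three values with exactly the requested mean, sample std and median.

    Lets a test reconstruct raw samples from published (mean, std, median)
    rows so aggregation arithmetic can be exercised end to end.
    """
    mu = (3 * mean - median) / 2
    delta = math.sqrt((2 * std**2 - (median - mean) ** 2 - 2 * (mu - mean) ** 2) / 2)
    lo, hi = mu - delta, mu + delta
    assert lo < median < hi, "requested statistics are not realisable with three values"
    return [lo, median, hi]


@pytest.fixture(scope="session")
def square_landmarks() -> LandmarkSet:
    """Symmetric 3-4-5 configuration: both AcI angles are atan(3/4)."""
    return LandmarkSet(RU=(60, 170), RD=(100, 200), LU=(340, 170), LD=(300, 200))


@pytest.fixture(scope="session")
def noiseless_cases():
    """A dozen noiseless phantoms of both classes for pipeline tests."""
    return generate_cases(12, seed=11, noise_sigma=0.0)


def random_landmark_sets(n: int, seed: int) -> list[LandmarkSet]:
    """Non-degenerate random landmark sets in a 512x512 canvas."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        pts = rng.uniform(20, 490, size=(4, 2))
        ru, rd, lu, ld = pts
        if (
            np.linalg.norm(ld - rd) > 1.0
            and np.linalg.norm(ru - rd) > 1.0
            and np.linalg.norm(lu - ld) > 1.0
        ):
            out.append(LandmarkSet(RU=ru, RD=rd, LU=lu, LD=ld))
    return out
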