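import numpy as np
import pytest

from prairieopt import compute_available_area
from prairieopt.synthetic import SyntheticSpec, generate_bundle, generate_worked_example


@pytest.fixture(scope="session")
def worked():
    """The fixed 6x6 two-species demonstration bundle."""
    return generate_worked_example()


@pytest.fixture(scope="session")
def small_bundle():
    """A 60x60 five-species synthetic landscape (seed 11)."""
    return generate_bundle(SyntheticSpec(seed=11, n_rows=60, n_cols=60))


@pytest.fixture(scope="session")
def small_available(small_bundle):
    bundle, _ = small_bundle
    return compute_available_area(bundle.habitat, bundle.landcover)


def random_problem(rng: np.random.Generator, n_max: int = 15, n_habitats: int = 3):
    """A random small selection instance (uniform pixel areas).

    Returns (benefit, cost, habitat_code, max_pixels, minima) where the
    minima are drawn to be binding about half the time.
    """
    n = int(rng.integers(4, n_max + 1))
    benefit = rng.uniform(0, 1, n)
    if rng.random() < 0.15:
        benefit[:] = 0.0  # exercise the zero-benefit branch
    cost = rng.uniform(0.5, 5.0, n)
    habitat = rng.integers(1, n_habitats + 1, n)
    max_pixels = int(rng.integers(1, n))
    minima = {}
    if rng.random() < 0.7:
        budget = max_pixels
        for code in np.unique(habitat):
            avail = int((habitat == code).sum())
            k = int(rng.integers(0, min(avail, budget) + 1))
            if k:
                minima[int(code)] = k
                budget -= k
            if budget == 0:
                break
    return benefit, cost, habitat, max_pixels, minima


def enumerate_optimum_capped(benefit, cost, habitat, max_pixels, minima):
    """Oracle over all subsets of size <= max_pixels (for larger n)."""
    import itertools

    n = len(benefit)
    ratio = np.asarray(benefit) / np.asarray(cost)
    habitat = np.asarray(habitat)
    best = -np.inf
    for k in range(max_pixels + 1):
        for comb in itertools.combinations(range(n), k):
            members = list(comb)
            if any(
                int((habitat[members] == code).sum()) < need
                for code, need in minima.items()
            ):
                continue
            obj = float(ratio[members].sum()) if members else 0.0
            if obj > best:
                best = obj
    return best


def enumerate_optimum(benefit, cost, habitat, max_pixels, minima):
    """Exhaustive-search oracle over all 2^n subsets (n <= ~18).

    Subset membership is materialized as a (2^n, n) bit matrix so the
    whole search is three matrix reductions.
    """
    n = len(benefit)
    ratio = np.asarray(benefit) / np.asarray(cost)
    habitat = np.asarray(habitat)
    members = (np.arange(1 << n)[:, None] >> np.arange(n)) & 1
    feasible = members.sum(axis=1) <= max_pixels
    for code, k in minima.items():
        feasible &= members[:, habitat == code].sum(axis=1) >= k
    if not feasible.any():
        return -np.inf
    return float((members @ ratio)[feasible].max())
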