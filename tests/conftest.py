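import numpy as np
import pytest

from ifser.stats_core import ClassFeatureStats, EffectiveRangeTable, LabeledMatrix


def standardized_base(n: int, seed: int = 0) -> np.ndarray:
    """A length-n vector with exact sample mean 0 and sample sd 1 (ddof=1)."""
    rng = np.random.default_rng(seed)
    b = rng.standard_normal(n)
    b -= b.mean()
    return b / b.std(ddof=1)


def matrix_with_exact_stats(mu, sigma, n_per_class, seed: int = 0) -> LabeledMatrix:
    """Build a LabeledMatrix whose per-class sample mean/sd equal mu/sigma.

    mu, sigma: (d, l) arrays; the samples of class j for feature i are
    mu[i, j] + sigma[i, j] * b with b standardized, so the empirical effective
    ranges are exactly the prescribed ones.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    d, l = mu.shape
    blocks = []
    labels = []
    for j, nj in enumerate(n_per_class):
        b = standardized_base(nj, seed=seed + j)
        blocks.append(mu[:, j][None, :] + np.outer(b, sigma[:, j]))
        labels += [f"c{j + 1}"] * nj
    return LabeledMatrix(values=np.vstack(blocks), labels=np.array(labels))


def table_from_ranges(ranges_per_feature, gamma: float = 1.732) -> EffectiveRangeTable:
    """EffectiveRangeTable from [[(lo, hi), ...] per feature] literals."""
    arr = np.asarray(ranges_per_feature, dtype=float)  # (d, l, 2)
    return EffectiveRangeTable(lower=arr[:, :, 0], upper=arr[:, :, 1], gamma=gamma)


def stats_for_table(table: EffectiveRangeTable, class_size) -> ClassFeatureStats:
    """Shape-consistent stats for a handcrafted range table (midpoint means)."""
    class_size = np.asarray(class_size, dtype=int)
    prior = class_size / class_size.sum()
    mu = (table.lower + table.upper) / 2
    sigma = (table.upper - table.lower) / 2
    return ClassFeatureStats(
        mu=mu,
        sigma=sigma,
        prior=prior,
        class_size=class_size,
        classes=np.array([f"c{j + 1}" for j in range(len(class_size))]),
    )


def random_range_table(rng, d: int, l: int) -> EffectiveRangeTable:
    """Random effective-range table (includes occasional zero-width ranges)."""
    centers = rng.normal(0, 2, size=(d, l))
    widths = rng.exponential(1.0, size=(d, l))
    widths[rng.random((d, l)) < 0.05] = 0.0
    return EffectiveRangeTable(lower=centers - widths / 2, upper=centers + widths / 2, gamma=1.732)


@pytest.fixture
def rng():
    return np.random.default_rng(20140204)


@pytest.fixture
def two_class_data(rng) -> LabeledMatrix:
    """30 samples, 5 features; feature 0 separates the classes, rest are noise."""
    n = 15
    x = rng.standard_normal((2 * n, 5))
    x[n:, 0] += 5.0
    labels = np.array(["a"] * n + ["b"] * n)
    return LabeledMatrix(values=x, labels=labels)
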