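"""Per-class summary statistics and effective ranges.

The effective range of class ``j`` for feature ``i`` is the interval

    R_ij = [mu_ij - (1 - p_j) * gamma * sigma_ij,
            mu_ij + (1 - p_j) * gamma * sigma_ij]

where ``mu_ij`` and ``sigma_ij`` are the class-conditional mean and standard
deviation, ``p_j`` is the class prior and ``gamma`` a Chebyshev-derived
multiplier.  The ``(1 - p_j)`` factor shrinks the range of prevalent classes,
which otherwise dominate through their larger spread.  By the Chebyshev
inequality ``P(|X - mu| >= gamma * sigma) <= 1/gamma**2`` for *any*
distribution, so the unscaled interval ``mu +/- gamma * sigma`` with
``gamma = 1.732`` holds at least two thirds of a class's mass; the scaled
effective range trades part of that guarantee for class-size balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_GAMMA",
    "LabeledMatrix",
    "ClassFeatureStats",
    "EffectiveRangeTable",
    "compute_class_stats",
    "chebyshev_gamma",
    "effective_ranges",
]

#: Chebyshev multiplier guaranteeing >= 2/3 coverage, the customary default.
DEFAULT_GAMMA = 1.732


@dataclass(frozen=True)
class LabeledMatrix:
    """A samples x features numeric matrix with one class label per sample.

    Parameters
    ----------
    values
        ``(N, d)`` float array; rows are samples, columns are features.
    labels
        Length-``N`` vector of class identifiers (any hashable dtype).
    feature_names
        Length-``d`` vector of feature identifiers.  Defaults to
        ``f0001 .. f000d``.

    Invariants enforced at construction: ``N >= 2``, ``d >= 1``, at least two
    distinct classes, every class holds at least two samples (so the sample
    standard deviation exists), and no non-finite values.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        n, d = values.shape
        if n < 2 or d < 1:
            raise ValueError(f"need N >= 2 samples and d >= 1 features, got N={n}, d={d}")
        if labels.shape != (n,):
            raise ValueError(f"labels must have shape ({n},), got {labels.shape}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))
            raise ValueError(
                f"non-finite values at (sample, feature) positions {bad[:5].tolist()}"
                + ("..." if len(bad) > 5 else "")
            )
        classes, counts = np.unique(labels, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        small = classes[counts < 2]
        if small.size:
            raise ValueError(f"classes with fewer than 2 samples: {small.tolist()}")
        if self.feature_names is None:
            width = len(str(d))
            names = np.array([f"f{i + 1:0{width}d}" for i in range(d)], dtype=object)
        else:
            names = np.asarray(self.feature_names, dtype=object)
            if names.shape != (d,):
                raise ValueError(f"feature_names must have shape ({d},), got {names.shape}")
            if len(set(names)) != d:
                raise ValueError("duplicate feature names")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", names)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass(frozen=True)
class ClassFeatureStats:
    """Per-(feature, class) mean/sd plus class priors and sizes.

    ``mu`` and ``sigma`` are ``(d, l)`` arrays; column ``j`` corresponds to
    ``classes[j]``.  ``prior`` sums to one; by default ``prior_j = K_j / N``.
    """

    mu: np.ndarray
    sigma: np.ndarray
    prior: np.ndarray
    class_size: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        d, l = self.mu.shape
        if self.sigma.shape != (d, l) or self.prior.shape != (l,) or self.class_size.shape != (l,):
            raise ValueError("inconsistent stats shapes")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")
        if not math.isclose(float(self.prior.sum()), 1.0, rel_tol=1e-9):
            raise ValueError("priors must sum to 1")

    @property
    def n_features(self) -> int:
        return self.mu.shape[0]

    @property
    def n_classes(self) -> int:
        return self.mu.shape[1]


@dataclass(frozen=True)
class EffectiveRangeTable:
    """Per-(feature, class) effective range ``[lower, upper]`` and its gamma."""

    lower: np.ndarray
    upper: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower/upper shape mismatch")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")

    @property
    def n_features(self) -> int:
        return self.lower.shape[0]

    @property
    def n_classes(self) -> int:
        return self.lower.shape[1]

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def compute_class_stats(
    data: LabeledMatrix,
    ddof: int = 1,
    priors: np.ndarray | None = None,
) -> ClassFeatureStats:
    """Class-conditional means, standard deviations, priors and sizes.

    Parameters
    ----------
    data
        The labeled matrix.
    ddof
        Delta degrees of freedom for the standard deviation; the default 1
        gives the unbiased sample convention, appropriate for the small class
        sizes typical of expression data.  Use 0 for the population form.
    priors
        Optional length-``l`` override for the class priors (in the order of
        ``data.classes``); must sum to 1.  Defaults to empirical frequencies
        ``K_j / N``.
    """
    classes = data.classes
    n, d = data.values.shape
    l = len(classes)
    mu = np.empty((d, l))
    sigma = np.empty((d, l))
    class_size = np.empty(l, dtype=int)
    for j, cls in enumerate(classes):
        block = data.values[data.labels == cls]
        class_size[j] = block.shape[0]
        mu[:, j] = block.mean(axis=0)
        sigma[:, j] = block.std(axis=0, ddof=ddof)
    if priors is None:
        prior = class_size / n
    else:
        prior = np.asarray(priors, dtype=float)
        if prior.shape != (l,):
            raise ValueError(f"priors must have shape ({l},)")
        if np.any(prior < 0) or not math.isclose(float(prior.sum()), 1.0, rel_tol=1e-9):
            raise ValueError("priors must be nonnegative and sum to 1")
    return ClassFeatureStats(mu=mu, sigma=sigma, prior=prior, class_size=class_size, classes=classes)


def chebyshev_gamma(min_fraction: float) -> float:
    """Smallest multiplier ``gamma`` whose Chebyshev bound guarantees coverage.

    ``P(|X - mu| >= gamma*sigma) <= 1/gamma**2`` holds for every distribution,
    so ``gamma = sqrt(1 / (1 - min_fraction))`` places at least
    ``min_fraction`` of the mass inside ``mu +/- gamma*sigma``.  With
    ``min_fraction = 2/3`` this gives 1.732 (i.e. sqrt(3)).
    """
    if not 0.0 < min_fraction < 1.0:
        raise ValueError(f"min_fraction must lie in (0, 1), got {min_fraction}")
    return math.sqrt(1.0 / (1.0 - min_fraction))


def effective_ranges(stats: ClassFeatureStats, gamma: float = DEFAULT_GAMMA) -> EffectiveRangeTable:
    """Build the per-(feature, class) effective ranges ``mu +/- (1-p)*gamma*sigma``."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    half = (1.0 - stats.prior)[np.newaxis, :] * gamma * stats.sigma
    return EffectiveRangeTable(lower=stats.mu - half, upper=stats.mu + half, gamma=float(gamma))
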