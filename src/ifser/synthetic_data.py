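"""Synthetic labeled matrices with planted class structure.

The generator emulates the regime of small-n / large-d expression studies:
a few dozen samples per class, class-conditional continuous features, and a
minority of genuinely class-separating features among pure noise.  Two kinds
of informative features are planted:

* mean-shift: class-conditional Gaussians whose means are staggered by
  ``separation`` standard deviations — disjoint effective ranges at large
  separation;
* inclusion: equal class means but class standard deviations doubling from
  class to class (variance ratio >= 4 between neighbours), so the tighter
  class's effective range nests inside the wider one's — the configuration
  the including area was designed to detect.

Noise features are identically distributed across classes.  A scaled-t option
exercises the distribution-free Chebyshev guarantee with heavy tails.  All
randomness flows from the spec's seed, so regeneration is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .stats_core import LabeledMatrix

__all__ = ["SyntheticSpec", "generate", "write_ground_truth", "read_ground_truth"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults plant 20 informative mean-shift features at 3-sigma separation
    among 200 total, with 50 samples in each of two classes.
    """

    n_per_class: tuple[int, ...] = (50, 50)
    d_total: int = 200
    d_informative: int = 20
    separation: float = 3.0
    noise_sigma: float = 1.0
    inclusion_fraction: float = 0.0
    seed: int = 0
    family: str = "gaussian"
    t_df: float = 3.0

    def __post_init__(self) -> None:
        if len(self.n_per_class) < 2:
            raise ValueError("need at least 2 classes")
        if any(n < 2 for n in self.n_per_class):
            raise ValueError("every class needs at least 2 samples")
        if not 0 <= self.d_informative <= self.d_total:
            raise ValueError("d_informative must lie in [0, d_total]")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if not 0.0 <= self.inclusion_fraction <= 1.0:
            raise ValueError("inclusion_fraction must lie in [0, 1]")
        if self.family not in ("gaussian", "t"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "t" and self.t_df <= 2:
            raise ValueError("t_df must exceed 2 so the variance exists")


def _draw(rng: np.random.Generator, spec: SyntheticSpec, size: tuple[int, ...]) -> np.ndarray:
    """Zero-mean, unit-variance noise of the requested family."""
    if spec.family == "gaussian":
        return rng.standard_normal(size)
    df = spec.t_df
    return rng.standard_t(df, size) / np.sqrt(df / (df - 2.0))


def generate(spec: SyntheticSpec) -> tuple[LabeledMatrix, frozenset[int]]:
    """Generate a labeled matrix and the set of planted informative indices.

    The first ``d_informative`` columns are informative — the first
    ``round(inclusion_fraction * d_informative)`` of them inclusion-type, the
    rest mean-shift — followed by noise columns.  Mean-shift class ``j`` is
    centred at ``j * separation * noise_sigma``; inclusion-type class ``j``
    has mean 0 and standard deviation ``noise_sigma * 2**j``.
    """
    rng = np.random.default_rng(spec.seed)
    l = len(spec.n_per_class)
    n = int(sum(spec.n_per_class))
    d = spec.d_total
    labels = np.repeat([f"c{j + 1}" for j in range(l)], spec.n_per_class)
    values = _draw(rng, spec, (n, d)) * spec.noise_sigma

    n_incl = round(spec.inclusion_fraction * spec.d_informative)
    informative = frozenset(range(spec.d_informative))
    start = 0
    for j, nj in enumerate(spec.n_per_class):
        rows = slice(start, start + nj)
        # inclusion-type: rescale the unit noise so class variances nest
        values[rows, :n_incl] *= 2.0 ** j
        # mean-shift: stagger the class means along the separation axis
        values[rows, n_incl:spec.d_informative] += j * spec.separation * spec.noise_sigma
        start += nj
    width = len(str(d))
    names = np.array(
        [
            ("inc" if i < n_incl else "sig" if i < spec.d_informative else "noise")
            + f"{i + 1:0{width}d}"
            for i in range(d)
        ],
        dtype=object,
    )
    return LabeledMatrix(values=values, labels=labels, feature_names=names), informative


def write_ground_truth(indices: frozenset[int], path: str | Path) -> None:
    """Write planted feature indices (0-based) one per line."""
    Path(path).write_text("".join(f"{i}\n" for i in sorted(indices)))


def read_ground_truth(path: str | Path) -> frozenset[int]:
    return frozenset(int(line) for line in Path(path).read_text().split())
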