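"""Final feature weights, rankings and top-k selection.

The full score multiplies the area term by the proportion term,

    W_i = V_i * Z_i,    V_i = NAC_i,    Z_i = NH_i + GH_i,

so a feature must have both a small (normalized) confusion area and few
samples inside its overlap/inclusion regions to rank highly.  W lies in
[0, 2]; the OA-only predecessor ranks by NAC alone (W in [0, 1]).  Rankings
sort by descending weight with ties broken by ascending feature index, which
makes them deterministic across runs and platforms.

:class:`EffectiveRangeSelector` wraps the ranking as a scikit-learn selector
so it can sit inside a ``Pipeline`` and be fitted on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .area_scoring import AreaScores, area_decomposition
from .proportion_scoring import ProportionScores, proportion_scores
from .stats_core import DEFAULT_GAMMA, LabeledMatrix, compute_class_stats, effective_ranges

__all__ = ["FeatureWeights", "ifser_weights", "ergs_rank", "select_top_k", "EffectiveRangeSelector"]


@dataclass(frozen=True)
class FeatureWeights:
    """Per-feature area term ``v``, proportion term ``z``, weight ``w = v*z``,
    and the induced ranking (0-based feature indices, best first)."""

    v: np.ndarray
    z: np.ndarray
    w: np.ndarray
    ranking: np.ndarray
    method: str
    areas: AreaScores | None = None
    proportions: ProportionScores | None = None

    @property
    def n_features(self) -> int:
        return len(self.w)


def _rank(w: np.ndarray) -> np.ndarray:
    # stable sort on -w keeps ascending index order within ties
    return np.argsort(-w, kind="stable")


def ifser_weights(
    data: LabeledMatrix,
    gamma: float = DEFAULT_GAMMA,
    *,
    mode: str = "sorted",
    exclusive: bool = False,
    include_ia: bool = True,
    use_proportions: bool = True,
    inclusion_convention: str = "included",
    ddof: int = 1,
    priors: np.ndarray | None = None,
) -> FeatureWeights:
    """Run the full pipeline: stats -> ranges -> areas -> proportions -> W.

    Parameters
    ----------
    data
        The labeled matrix.
    gamma
        Chebyshev multiplier for the effective ranges.
    mode, exclusive, include_ia
        Passed to the area decomposition; ``include_ia=False`` zeroes the
        including area.
    use_proportions
        When False, ``Z`` is fixed to 1 and ``W`` reduces to the NAC — with
        ``include_ia=False`` as well, this is exactly the OA-only predecessor.
    inclusion_convention
        Which samples count toward ``G`` (see proportion scoring).
    ddof, priors
        Forwarded to the class statistics.
    """
    stats = compute_class_stats(data, ddof=ddof, priors=priors)
    ranges = effective_ranges(stats, gamma)
    areas = area_decomposition(ranges, mode=mode, include_ia=include_ia, exclusive=exclusive)
    v = areas.nac
    if use_proportions:
        props = proportion_scores(data, stats, ranges, mode=mode, convention=inclusion_convention)
        z = props.nh + props.gh
    else:
        props = None
        z = np.ones_like(v)
    w = v * z
    return FeatureWeights(
        v=v, z=z, w=w, ranking=_rank(w), method="ifser", areas=areas, proportions=props
    )


def ergs_rank(
    data: LabeledMatrix,
    gamma: float = DEFAULT_GAMMA,
    *,
    mode: str = "sorted",
    ddof: int = 1,
    priors: np.ndarray | None = None,
) -> FeatureWeights:
    """OA-only ranking: ``W = NAC`` of the overlapping area, ``Z = 1``."""
    fw = ifser_weights(
        data, gamma, mode=mode, include_ia=False, use_proportions=False, ddof=ddof, priors=priors
    )
    return FeatureWeights(
        v=fw.v, z=fw.z, w=fw.w, ranking=fw.ranking, method="ergs",
        areas=fw.areas, proportions=None,
    )


def select_top_k(weights: FeatureWeights, k: int) -> np.ndarray:
    """First ``k`` feature indices of the ranking (0-based), order preserved."""
    d = weights.n_features
    if not 1 <= k <= d:
        raise ValueError(f"k must lie in [1, {d}], got {k}")
    return weights.ranking[:k].copy()


class EffectiveRangeSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn feature selector ranking by effective-range weights.

    Parameters
    ----------
    n_features_to_select : int, default=10
        Number of top-ranked features to keep.
    method : {"ifser", "ergs"}, default="ifser"
        Full weight (area x proportions) or OA-only NAC.
    gamma : float, default=1.732
        Chebyshev multiplier.
    mode : {"sorted", "literal"}, default="sorted"
        Class-pair orientation for the area sums.
    exclusive : bool, default=False
        De-duplicate the included region inside SA.
    inclusion_convention : {"included", "both"}, default="included"
        Which samples count toward G.
    ddof : int, default=1
        Standard-deviation convention.

    Attributes
    ----------
    weights_ : FeatureWeights
        Full scoring detail from the training data.
    ranking_ : ndarray
        Feature indices, best first.
    """

    def __init__(
        self,
        n_features_to_select: int = 10,
        method: str = "ifser",
        gamma: float = DEFAULT_GAMMA,
        mode: str = "sorted",
        exclusive: bool = False,
        inclusion_convention: str = "included",
        ddof: int = 1,
    ) -> None:
        self.n_features_to_select = n_features_to_select
        self.method = method
        self.gamma = gamma
        self.mode = mode
        self.exclusive = exclusive
        self.inclusion_convention = inclusion_convention
        self.ddof = ddof

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        data = LabeledMatrix(values=np.asarray(X, dtype=float), labels=np.asarray(y))
        if self.method == "ifser":
            self.weights_ = ifser_weights(
                data,
                self.gamma,
                mode=self.mode,
                exclusive=self.exclusive,
                inclusion_convention=self.inclusion_convention,
                ddof=self.ddof,
            )
        elif self.method == "ergs":
            self.weights_ = ergs_rank(data, self.gamma, mode=self.mode, ddof=self.ddof)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.ranking_ = self.weights_.ranking
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[select_top_k(self.weights_, self.n_features_to_select)] = True
        return mask
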