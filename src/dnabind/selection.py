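"""Feature ranking and selection.

Minimum-redundancy maximum-relevance (mRMR) greedy forward selection over
discretised features, in its two classic forms: MID (mutual-information
difference — relevance minus mean redundancy) and MIQ (quotient — relevance
over mean redundancy).  Also a PCA-based attribute-contribution ranking that
attributes each principal component's explained-variance share back to the
original features through squared loadings.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = [
    "MRMRResult",
    "ContributionRanking",
    "discretize",
    "mutual_information",
    "mrmr_select",
    "pca_contribution",
]

MIQ_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class MRMRResult:
    """Ordered selection with the criterion value at each step."""

    features: tuple[str, ...]
    scores: tuple[float, ...]
    method: str  # "MID" | "MIQ"
    bin_scheme: str

    def to_frame(self) -> pd.DataFrame:
        """Table with columns order / feature / score (1-based order)."""
        return pd.DataFrame(
            {
                "order": np.arange(1, len(self.features) + 1),
                "feature": self.features,
                "score": self.scores,
            }
        )


@dataclasses.dataclass(frozen=True)
class ContributionRanking:
    features: tuple[str, ...]
    contributions: tuple[float, ...]  # aligned with features, descending
    cumulative_variance: tuple[float, ...]  # per component count


def discretize(
    matrix: pd.DataFrame, scheme: str = "three_state_sigma", alpha: float = 1.0
) -> pd.DataFrame:
    """Map each feature to states {-1, 0, +1} around mean +/- alpha*sd.

    Values strictly below mean - alpha*sd map to -1, strictly above
    mean + alpha*sd to +1, the rest to 0.  Constant features become all-0.
    """
    if scheme != "three_state_sigma":
        raise ValueError(f"unknown discretization scheme: {scheme!r}")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("feature matrix contains non-finite values")
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    lo = mean - alpha * sd
    hi = mean + alpha * sd
    states = np.zeros_like(values, dtype=np.int8)
    states[values < lo] = -1
    states[values > hi] = 1
    return pd.DataFrame(states, index=matrix.index, columns=matrix.columns)


def mutual_information(x: Sequence[int], y: Sequence[int]) -> float:
    """Mutual information in bits between two discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size == 0:
        raise ValueError("vectors must be non-empty")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log2(joint[mask] / (px @ py)[mask])))


def mrmr_select(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    k: int,
    method: str = "MID",
    alpha: float = 1.0,
) -> MRMRResult:
    """Greedy mRMR forward selection of up to k features.

    Features are discretised with the three-state mean±sd scheme; the first
    pick maximises relevance I(f; label); subsequent picks maximise
    relevance − mean redundancy (MID) or relevance / mean redundancy (MIQ)
    against the already-selected set.  Ties break to the lower feature index.
    """
    method = method.upper()
    if method not in ("MID", "MIQ"):
        raise ValueError(f"method must be MID or MIQ, got {method!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least 2 classes")
    disc = discretize(matrix, alpha=alpha)
    X = disc.to_numpy()
    names = list(matrix.columns)
    n_feat = X.shape[1]
    if k > n_feat:
        warnings.warn(
            f"k={k} exceeds feature count {n_feat}; truncating", stacklevel=2
        )
        k = n_feat

    relevance = np.array([mutual_information(X[:, j], y) for j in range(n_feat)])
    # pairwise feature MI filled lazily as features get selected
    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(n_feat)
    available = np.ones(n_feat, dtype=bool)
    for step in range(k):
        if step == 0:
            criterion = relevance.copy()
        else:
            mean_red = redundancy_sum / len(selected)
            if method == "MID":
                criterion = relevance - mean_red
            else:
                criterion = relevance / np.maximum(mean_red, MIQ_EPS)
        criterion = np.where(available, criterion, -np.inf)
        best = int(np.argmax(criterion))  # argmax takes first => lowest index tie-break
        selected.append(best)
        scores.append(float(criterion[best]))
        available[best] = False
        col = X[:, best]
        for j in np.nonzero(available)[0]:
            redundancy_sum[j] += mutual_information(X[:, j], col)
    return MRMRResult(
        features=tuple(names[i] for i in selected),
        scores=tuple(scores),
        method=method,
        bin_scheme=f"three_state_sigma(alpha={alpha})",
    )


def pca_contribution(
    matrix: pd.DataFrame, n_top_components: int | None = None
) -> ContributionRanking:
    """Rank features by their contribution to the top principal components.

    Features are standardised, PCA fitted, and each feature's contribution is
    the sum over the top components of (squared loading × that component's
    explained-variance ratio).  With all components retained the
    contributions sum to 1.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    X = StandardScaler().fit_transform(matrix.to_numpy(dtype=float))
    # zero-variance columns standardise to 0 and contribute nothing
    X = np.nan_to_num(X)
    n_max = min(X.shape)
    if n_top_components is None:
        n_top_components = n_max
    n_top_components = min(n_top_components, n_max)
    pca = PCA(n_components=n_max, svd_solver="full")
    pca.fit(X)
    evr = pca.explained_variance_ratio_
    loadings = pca.components_  # components x features, unit rows
    contrib = (loadings[:n_top_components] ** 2 * evr[:n_top_components, None]).sum(
        axis=0
    )
    order = np.argsort(-contrib, kind="stable")
    names = np.array(matrix.columns)
    return ContributionRanking(
        features=tuple(names[order]),
        contributions=tuple(float(c) for c in contrib[order]),
        cumulative_variance=tuple(float(v) for v in np.cumsum(evr)),
    )
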