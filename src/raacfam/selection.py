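"""Feature ranking by ANOVA F-score and incremental feature selection (IFS).

Each feature is scored by the two-group one-way ANOVA F statistic — the
between-class mean square over the pooled within-class mean square — so a
feature whose class means are far apart relative to its within-class spread
ranks high.  IFS then sweeps nested prefixes of the ranked list, scoring
each prefix by cross-validated classifier accuracy, and selects the
smallest prefix length attaining the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DatasetError
from .features import FeatureMatrix

TIE_POLICY = "descending F, ties broken by ascending feature index"


@dataclass
class FeatureRanking:
    """Per-feature F scores and the induced ranking.

    ``scores`` are finite and >= 0; features with zero within-class variance
    but separated class means (an infinite raw F) are capped to the largest
    finite score and placed first in ``order``.
    """

    scores: np.ndarray
    order: np.ndarray
    tie_policy: str = TIE_POLICY

    def top(self, d: int) -> np.ndarray:
        return self.order[:d]


def anova_f_scores(X, labels=None) -> FeatureRanking:
    """Rank features of a two-class matrix by the one-way ANOVA F statistic.

    Parameters
    ----------
    X : FeatureMatrix or array of shape (n_samples, n_features)
        If an array, ``labels`` must be given (binary 0/1).

    Notes
    -----
    For two groups a and b with sizes n_a, n_b and grand mean m:

        MS_between = n_a (m_a - m)^2 + n_b (m_b - m)^2          (df = 1)
        MS_within  = (SS_a + SS_b) / (n - 2)

    Degenerate features: all-constant ones score 0; zero-within-variance
    features with distinct class means rank first with the score capped at
    the largest finite F observed.
    """
    if isinstance(X, FeatureMatrix):
        values, labels = X.values, X.labels
    else:
        values = np.asarray(X, dtype=float)
        if labels is None:
            raise DatasetError("labels required when X is a plain array")
        labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise DatasetError(f"need exactly 2 classes (got {len(classes)})")
    n = values.shape[0]
    if n < 4:
        raise DatasetError(f"need at least 4 samples (got {n})")
    masks = [labels == c for c in classes]
    sizes = np.array([m.sum() for m in masks])
    if sizes.min() < 2:
        raise DatasetError("each class needs at least 2 samples")

    grand = values.mean(axis=0)
    ss_between = np.zeros(values.shape[1])
    ss_within = np.zeros(values.shape[1])
    for mask, n_g in zip(masks, sizes):
        group = values[mask]
        mean_g = group.mean(axis=0)
        ss_between += n_g * (mean_g - grand) ** 2
        ss_within += ((group - mean_g) ** 2).sum(axis=0)
    ms_between = ss_between  # df = k - 1 = 1
    ms_within = ss_within / (n - 2)

    # Zero-variance detection must be scale-aware: an exactly constant
    # column accumulates O(eps^2) rounding noise in both sums of squares,
    # whose ratio is an arbitrary finite number.
    col_scale = np.maximum(np.abs(values).max(axis=0), np.abs(grand)) ** 2
    tol = n * (col_scale + np.finfo(float).tiny) * 1e-24
    zero_within = ss_within <= tol
    zero_between = ss_between <= tol

    raw = np.zeros(values.shape[1])
    ok = ~zero_within
    raw[ok] = ms_between[ok] / ms_within[ok]
    perfect = zero_within & ~zero_between
    raw[perfect] = np.inf
    raw[zero_within & zero_between] = 0.0  # all-constant features

    order = np.lexsort((np.arange(len(raw)), -raw))
    scores = raw.copy()
    if perfect.any():
        finite = scores[np.isfinite(scores)]
        cap = float(finite.max()) if finite.size and finite.max() > 0 else 1.0
        scores[perfect] = cap
    return FeatureRanking(scores=scores, order=order)


@dataclass
class IFSResult:
    """Accuracy-versus-dimension curve from incremental feature selection."""

    curve: list[tuple[int, float]]
    best_dimension: int
    best_accuracy: float
    svm_params: tuple[float, float]  # (C, gamma) used for the sweep

    def to_rows(self):
        return [{"dimension": d, "cv_accuracy": a} for d, a in self.curve]


def incremental_feature_selection(
    X: FeatureMatrix,
    ranking: FeatureRanking,
    svm_config=None,
    *,
    step: int = 1,
    max_dim: int | None = None,
    retune: bool = False,
) -> IFSResult:
    """Sweep nested prefixes of the ranked feature list by CV accuracy.

    Dimensions ``step, 2*step, ...`` up to ``max_dim`` (default all
    features; the final dimension is always included).  By default the SVM
    hyperparameters are fixed by one grid search at full dimension and the
    sweep re-uses them; ``retune=True`` re-runs the grid at every prefix
    (slower, rarely changes the selected dimension).

    Returns the full curve; ``best_dimension`` is the smallest dimension
    attaining the maximum accuracy.
    """
    from .model import SVMConfig, grid_search, pooled_cv_accuracy

    if svm_config is None:
        svm_config = SVMConfig()
    if step < 1:
        raise ConfigError(f"step must be >= 1 (got {step})")
    n_feat = X.n_features
    if max_dim is None:
        max_dim = n_feat
    if not 1 <= max_dim <= n_feat:
        raise ConfigError(f"max_dim must be in 1..{n_feat} (got {max_dim})")

    dims = list(range(step, max_dim + 1, step))
    if not dims or dims[-1] != max_dim:
        dims.append(max_dim)

    if retune:
        fixed = None
    else:
        best = grid_search(X.subset(ranking.order[:max_dim]), X.labels, svm_config)
        fixed = (best.C, best.gamma)

    curve: list[tuple[int, float]] = []
    for d in dims:
        cols = X.subset(ranking.top(d))
        if retune:
            cell = grid_search(cols, X.labels, svm_config)
            acc, params = cell.cv_accuracy, (cell.C, cell.gamma)
        else:
            acc = pooled_cv_accuracy(
                cols, X.labels, fixed[0], fixed[1], svm_config
            )
            params = fixed
        curve.append((d, float(acc)))

    accs = np.array([a for _, a in curve])
    best_i = int(np.argmax(accs))  # argmax returns the first (smallest d) maximum
    return IFSResult(
        curve=curve,
        best_dimension=curve[best_i][0],
        best_accuracy=float(accs[best_i]),
        svm_params=params if retune else fixed,
    )


def ranking_to_rows(ranking: FeatureRanking, feature_names) -> list[dict]:
    """Ranked (feature, score, rank) rows for TSV export."""
    return [
        {
            "feature": feature_names[j],
            "score": float(ranking.scores[j]),
            "rank": r + 1,
        }
        for r, j in enumerate(ranking.order)
    ]
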