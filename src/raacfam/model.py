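"""RBF-SVM training with grid search, cross-validation, and the top-level
Model/Results objects.

The classifier is a support vector machine with a radial basis function
kernel; the regularization constant C and kernel width gamma are chosen by
an exhaustive search over a geometric lattice within 2^-5 < C < 2^15 and
2^-15 < gamma < 2^3, scoring each pair by stratified k-fold cross-validated
accuracy (pooled out-of-fold predictions).  Ties favour smaller C, then
smaller gamma.  K-mer compositions are already bounded in [0, 1], so no
further feature scaling is applied.

:class:`ProteinFamilyModel` is the user-facing entry point: build it from
FASTA files or sequences, call :meth:`~ProteinFamilyModel.fit`, and read
estimates and diagnostics off the returned
:class:`ProteinFamilyResults` (``summary()``, ``predict()``, ``save()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import __about__
from .alphabet import ReductionScheme, get_type33
from .errors import ConfigError, DatasetError
from .features import (
    FeatureMatrix,
    FeatureSpec,
    encode_dataset,
    encode_sequences,
    read_fasta,
)
from .metrics import EvalReport, evaluate_predictions
from .selection import (
    FeatureRanking,
    IFSResult,
    anova_f_scores,
    incremental_feature_selection,
)

_C_BOUNDS = (2.0**-5, 2.0**15)
_GAMMA_BOUNDS = (2.0**-15, 2.0**3)

MODEL_FORMAT_VERSION = 1


def _default_grid(lo_exp: int, hi_exp: int, step: int) -> tuple[float, ...]:
    return tuple(2.0**e for e in range(lo_exp, hi_exp + 1, step))


@dataclass(frozen=True)
class SVMConfig:
    """Grid-search and cross-validation settings.

    Defaults: C over 2^-4..2^14 and gamma over 2^-14..2^2, both with
    exponent step 2 (strictly inside the open search intervals), scored by
    10-fold stratified CV.
    """

    c_grid: tuple[float, ...] = _default_grid(-4, 14, 2)
    gamma_grid: tuple[float, ...] = _default_grid(-14, 2, 2)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.c_grid or not self.gamma_grid:
            raise ConfigError("C and gamma grids must be non-empty")
        for c in self.c_grid:
            if not _C_BOUNDS[0] < c < _C_BOUNDS[1]:
                raise ConfigError(f"C={c} outside the open interval (2^-5, 2^15)")
        for g in self.gamma_grid:
            if not _GAMMA_BOUNDS[0] < g < _GAMMA_BOUNDS[1]:
                raise ConfigError(
                    f"gamma={g} outside the open interval (2^-15, 2^3)"
                )
        if self.cv_folds < 2:
            raise ConfigError(f"cv_folds must be >= 2 (got {self.cv_folds})")


def make_folds(y: np.ndarray, config: SVMConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified fold assignment; validates that every fold sees
    both classes."""
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    folds = list(skf.split(np.zeros(len(y)), y))
    for i, (train, test) in enumerate(folds):
        for part, name in ((train, "training"), (test, "test")):
            if len(np.unique(y[part])) < 2 and name == "training":
                raise DatasetError(f"fold {i}: {name} split is missing a class")
    return folds


def _svc(C: float, gamma: float, seed: int, probability: bool = False) -> SVC:
    kwargs = dict(kernel="rbf", C=C, gamma=gamma, random_state=seed)
    if probability:
        # passing probability explicitly (even False) trips a deprecation
        # warning in recent sklearn, so only set it when needed
        kwargs["probability"] = True
    return SVC(**kwargs)


def _out_of_fold(X, y, C, gamma, folds, seed, with_scores=False):
    """Pooled out-of-fold hard predictions (and decision scores)."""
    pred = np.empty(len(y), dtype=int)
    scores = np.empty(len(y)) if with_scores else None
    for train, test in folds:
        clf = _svc(C, gamma, seed).fit(X[train], y[train])
        pred[test] = clf.predict(X[test])
        if with_scores:
            scores[test] = clf.decision_function(X[test])
    return pred, scores


def pooled_cv_accuracy(X, y, C: float, gamma: float, config: SVMConfig) -> float:
    """Accuracy of pooled out-of-fold predictions at fixed (C, gamma)."""
    folds = make_folds(np.asarray(y), config)
    pred, _ = _out_of_fold(np.asarray(X), np.asarray(y), C, gamma, folds, config.seed)
    return float(np.mean(pred == y))


@dataclass(frozen=True)
class GridResult:
    C: float
    gamma: float
    cv_accuracy: float
    table: pd.DataFrame = field(repr=False, compare=False)


def grid_search(X, y, config: SVMConfig | None = None) -> GridResult:
    """Exhaustive (C, gamma) lattice search by pooled CV accuracy.

    The grid is traversed in ascending (C, gamma) order and only a strictly
    better accuracy replaces the incumbent, so ties resolve to the smallest
    C, then the smallest gamma.
    """
    if config is None:
        config = SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise DatasetError("grid_search needs both classes present")
    folds = make_folds(y, config)
    rows = []
    best: tuple[float, float, float] | None = None
    for C in sorted(config.c_grid):
        for gamma in sorted(config.gamma_grid):
            pred, _ = _out_of_fold(X, y, C, gamma, folds, config.seed)
            acc = float(np.mean(pred == y))
            rows.append({"C": C, "gamma": gamma, "cv_accuracy": acc})
            if best is None or acc > best[2]:
                best = (C, gamma, acc)
    table = pd.DataFrame(rows)
    return GridResult(C=best[0], gamma=best[1], cv_accuracy=best[2], table=table)


def cross_validate(
    X, y, C: float, gamma: float, config: SVMConfig | None = None
) -> tuple[EvalReport, list[EvalReport]]:
    """Stratified k-fold CV at fixed (C, gamma).

    Returns the pooled report (out-of-fold predictions of all folds scored
    together, including rank-statistic AUC from decision scores) and the
    per-fold reports.
    """
    if config is None:
        config = SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = make_folds(y, config)
    pred, scores = _out_of_fold(X, y, C, gamma, folds, config.seed, with_scores=True)
    pooled = evaluate_predictions(y, pred, scores)
    per_fold = [
        evaluate_predictions(y[test], pred[test], scores[test])
        for _, test in folds
    ]
    return pooled, per_fold


def _fit_probability_svc(X, y, C, gamma, seed) -> SVC:
    est = _svc(C, gamma, seed, probability=True)
    with warnings.catch_warnings():
        # sklearn 1.9 deprecates probability=True in favour of
        # CalibratedClassifierCV, which lacks decision_function; we need both.
        warnings.simplefilter("ignore", FutureWarning)
        est.fit(X, y)
    return est


def nested_cv_report(
    X, y, n_selected: int, C: float, gamma: float, config: SVMConfig
) -> tuple[EvalReport, list[EvalReport]]:
    """Pooled CV with feature ranking re-learned inside each training fold.

    Ranking features on the full dataset and then cross-validating on the
    selected columns leaks label information into the score (selection
    bias); with hundreds of candidate features the inflation is material.
    Here each fold ranks features on its training split only, takes the top
    ``n_selected``, and predicts its held-out split, so the pooled report
    is an honest estimate of the select-then-classify procedure.
    """
    from .selection import anova_f_scores

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = make_folds(y, config)
    pred = np.empty(len(y), dtype=int)
    scores = np.empty(len(y))
    for train, test in folds:
        fold_ranking = anova_f_scores(X[train], y[train])
        cols = fold_ranking.order[:n_selected]
        clf = _svc(C, gamma, config.seed).fit(X[train][:, cols], y[train])
        pred[test] = clf.predict(X[test][:, cols])
        scores[test] = clf.decision_function(X[test][:, cols])
    pooled = evaluate_predictions(y, pred, scores)
    per_fold = [
        evaluate_predictions(y[test], pred[test], scores[test]) for _, test in folds
    ]
    return pooled, per_fold


def grid_search_train(
    Xmat: FeatureMatrix,
    config: SVMConfig | None = None,
    feature_indices: Sequence[int] | None = None,
) -> "TrainedModel":
    """Grid-search (C, gamma) on the (optionally subset) feature matrix and
    refit on all data at the chosen pair."""
    if config is None:
        config = SVMConfig()
    if feature_indices is None:
        feature_indices = np.arange(Xmat.n_features)
    feature_indices = np.asarray(feature_indices, dtype=int)
    X = Xmat.subset(feature_indices)
    y = Xmat.labels
    best = grid_search(X, y, config)
    pooled, per_fold = cross_validate(X, y, best.C, best.gamma, config)
    estimator = _fit_probability_svc(X, y, best.C, best.gamma, config.seed)
    return TrainedModel(
        estimator=estimator,
        C=best.C,
        gamma=best.gamma,
        spec=Xmat.spec,
        selected_indices=feature_indices,
        cv_report=pooled,
        fold_reports=per_fold,
        config=config,
    )


@dataclass
class TrainedModel:
    """A fitted RBF-SVM plus everything needed to encode new sequences."""

    estimator: SVC
    C: float
    gamma: float
    spec: FeatureSpec
    selected_indices: np.ndarray
    cv_report: EvalReport
    fold_reports: list[EvalReport] = field(default_factory=list)
    config: SVMConfig = field(default_factory=SVMConfig)

    def __post_init__(self):
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        if self.selected_indices.size == 0:
            raise ConfigError("no features selected")
        if self.selected_indices.max() >= self.spec.n_features:
            raise ConfigError(
                "selected feature index exceeds the encoding dimension"
            )

    def predict_records(
        self, records: Iterable[tuple[str, str]], nonstandard_policy: str = "drop"
    ) -> pd.DataFrame:
        """Per-sequence label, decision score and positive-class probability.

        Sequences shorter than k are kept in the output table with status
        ``skipped`` and empty prediction columns.
        """
        records = list(records)
        if not records:
            raise DatasetError("no input sequences")
        rows = []
        pos_col = int(np.where(self.estimator.classes_ == 1)[0][0])
        for seq_id, seq in records:
            matrix, kept, skipped = encode_sequences(
                [(seq_id, seq)], self.spec, nonstandard_policy=nonstandard_policy
            )
            if skipped:
                rows.append(
                    {"id": seq_id, "label": pd.NA, "score": np.nan,
                     "probability": np.nan, "status": "skipped: shorter than k"}
                )
                continue
            x = matrix[:, self.selected_indices]
            rows.append(
                {
                    "id": seq_id,
                    "label": int(self.estimator.predict(x)[0]),
                    "score": float(self.estimator.decision_function(x)[0]),
                    "probability": float(self.estimator.predict_proba(x)[0, pos_col]),
                    "status": "ok",
                }
            )
        return pd.DataFrame(rows)

    def predict_fasta(self, fasta_path, nonstandard_policy: str = "drop") -> pd.DataFrame:
        return self.predict_records(read_fasta(fasta_path), nonstandard_policy)

    def save(self, path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "raacfam_version": __about__.__version__,
            "estimator": self.estimator,
            "C": self.C,
            "gamma": self.gamma,
            "scheme_type_id": self.spec.scheme.type_id,
            "scheme_spec": self.spec.scheme.spec_string,
            "k": self.spec.k,
            "selected_indices": self.selected_indices,
            "cv_report": self.cv_report.to_dict(),
            "config": self.config,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        from .alphabet import parse_scheme_string
        from .metrics import ConfusionCounts, EvalReport

        payload = joblib.load(path)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ConfigError(
                f"unsupported model file version {payload.get('format_version')}"
            )
        scheme = parse_scheme_string(
            payload["scheme_spec"], payload["scheme_type_id"]
        )
        spec = FeatureSpec(scheme, payload["k"])
        d = payload["cv_report"]
        report = EvalReport(
            counts=ConfusionCounts(d["tp"], d["tn"], d["fp"], d["fn"]),
            sn=d["sn"], sp=d["sp"], f1=d["f1"], acc=d["acc"], mcc=d["mcc"],
            auc=d.get("auc"), undefined=d.get("undefined", {}),
        )
        return cls(
            estimator=payload["estimator"],
            C=payload["C"],
            gamma=payload["gamma"],
            spec=spec,
            selected_indices=payload["selected_indices"],
            cv_report=report,
            config=payload["config"],
        )


class ProteinFamilyModel:
    """Two-class protein family classifier over a reduced-alphabet k-mer
    encoding.

    Parameters
    ----------
    data : FeatureMatrix
        Encoded, labelled samples (1 = family member, 0 = background).

    Construct via :meth:`from_fasta` or :meth:`from_sequences` to go
    straight from sequences; ``fit`` runs ANOVA ranking, optional IFS and
    the SVM grid search, returning a :class:`ProteinFamilyResults`.

    Examples
    --------
    >>> model = ProteinFamilyModel.from_fasta("pos.fasta", "neg.fasta",
    ...                                       scheme_size=15, k=2)
    >>> res = model.fit(ifs_step=15)
    >>> print(res.summary())
    """

    def __init__(self, data: FeatureMatrix):
        if len(np.unique(data.labels)) != 2:
            raise DatasetError("both classes must be present")
        self.data = data

    @classmethod
    def from_fasta(
        cls,
        pos_fasta,
        neg_fasta,
        *,
        scheme: ReductionScheme | None = None,
        scheme_size: int = 15,
        k: int = 2,
        nonstandard_policy: str = "drop",
    ) -> "ProteinFamilyModel":
        if scheme is None:
            scheme = get_type33(scheme_size)
        spec = FeatureSpec(scheme, k)
        return cls(encode_dataset(pos_fasta, neg_fasta, spec,
                                  nonstandard_policy=nonstandard_policy))

    @classmethod
    def from_sequences(
        cls,
        records: Iterable[tuple[str, str]],
        labels: Sequence[int],
        *,
        scheme: ReductionScheme | None = None,
        scheme_size: int = 15,
        k: int = 2,
        nonstandard_policy: str = "drop",
    ) -> "ProteinFamilyModel":
        if scheme is None:
            scheme = get_type33(scheme_size)
        spec = FeatureSpec(scheme, k)
        records = list(records)
        labels = np.asarray(labels, dtype=int)
        if len(records) != len(labels):
            raise DatasetError("records and labels disagree on n_samples")
        matrix, kept_ids, skipped = encode_sequences(
            records, spec, nonstandard_policy=nonstandard_policy
        )
        if skipped:
            keep = [i for i, (rid, _) in enumerate(records) if rid in set(kept_ids)]
            labels = labels[keep]
        return cls(FeatureMatrix(matrix, labels, kept_ids, spec))

    def fit(
        self,
        *,
        select: bool = True,
        ifs_step: int = 1,
        max_dim: int | None = None,
        retune: bool = False,
        svm_config: SVMConfig | None = None,
    ) -> "ProteinFamilyResults":
        """Rank features, optionally run IFS, grid-search the SVM and refit.

        With ``select=False`` the full feature set is used and only the
        grid search runs.

        The pooled CV diagnostics on the results object are computed with
        feature ranking re-learned inside each training fold (see
        :func:`nested_cv_report`); the IFS curve itself uses the
        conventional rank-once sweep and serves only to pick the dimension.
        """
        if svm_config is None:
            svm_config = SVMConfig()
        ranking = anova_f_scores(self.data)
        ifs: IFSResult | None = None
        if select:
            ifs = incremental_feature_selection(
                self.data, ranking, svm_config,
                step=ifs_step, max_dim=max_dim, retune=retune,
            )
            selected = ranking.top(ifs.best_dimension)
            X_sel = self.data.subset(selected)
            best = grid_search(X_sel, self.data.labels, svm_config)
            pooled, per_fold = nested_cv_report(
                self.data.values, self.data.labels,
                ifs.best_dimension, best.C, best.gamma, svm_config,
            )
            estimator = _fit_probability_svc(
                X_sel, self.data.labels, best.C, best.gamma, svm_config.seed
            )
            trained = TrainedModel(
                estimator=estimator, C=best.C, gamma=best.gamma,
                spec=self.data.spec, selected_indices=selected,
                cv_report=pooled, fold_reports=per_fold, config=svm_config,
            )
        else:
            trained = grid_search_train(
                self.data, svm_config, np.arange(self.data.n_features)
            )
        return ProteinFamilyResults(self, trained, ranking, ifs)


class ProteinFamilyResults:
    """Fit results: the trained SVM, feature ranking, IFS curve and pooled
    cross-validation diagnostics."""

    def __init__(
        self,
        model: ProteinFamilyModel,
        trained: TrainedModel,
        ranking: FeatureRanking,
        ifs: IFSResult | None,
    ):
        self.model = model
        self.trained = trained
        self.ranking = ranking
        self.ifs = ifs

    # -- convenience accessors -------------------------------------------
    @property
    def cv_report(self) -> EvalReport:
        return self.trained.cv_report

    @property
    def params(self) -> dict:
        return {"C": self.trained.C, "gamma": self.trained.gamma}

    @property
    def selected_features(self) -> list[str]:
        names = self.trained.spec.feature_names
        return [names[i] for i in self.trained.selected_indices]

    def predict(self, records_or_fasta) -> pd.DataFrame:
        """Classify new sequences: a FASTA path or (id, sequence) pairs."""
        if isinstance(records_or_fasta, (str, bytes)) or hasattr(
            records_or_fasta, "__fspath__"
        ):
            return self.trained.predict_fasta(records_or_fasta)
        return self.trained.predict_records(records_or_fasta)

    def save(self, path) -> None:
        self.trained.save(path)

    def ifs_curve_frame(self) -> pd.DataFrame:
        if self.ifs is None:
            raise ConfigError("model was fitted without feature selection")
        return pd.DataFrame(self.ifs.to_rows())

    def summary(self) -> str:
        spec = self.trained.spec
        scheme = spec.scheme
        r = self.cv_report
        c = r.counts
        lines = [
            "        Protein Family RAAC-SVM Classification Results",
            "=" * 64,
            f"Alphabet:        type {scheme.type_id}, {scheme.size} groups "
            f"({scheme.spec_string})",
            f"K-mer order:     {spec.k}   (encoding dimension {spec.n_features})",
            f"Samples:         {self.model.data.n_samples} "
            f"({int(self.model.data.labels.sum())} positive, "
            f"{int((1 - self.model.data.labels).sum())} negative)",
            f"Selected:        {len(self.trained.selected_indices)} features"
            + (
                f" (IFS best dimension, step {self.ifs.curve[0][0]})"
                if self.ifs is not None
                else " (no selection)"
            ),
            f"SVM:             RBF kernel, C = {self.trained.C:g}, "
            f"gamma = {self.trained.gamma:g}",
            f"CV:              {self.trained.config.cv_folds}-fold stratified, "
            f"seed {self.trained.config.seed}, pooled out-of-fold scoring",
            "-" * 64,
            f"Confusion:       TP={c.tp}  TN={c.tn}  FP={c.fp}  FN={c.fn}",
        ]

        def fmt(v):
            return "  undef" if v is None else f"{v:7.4f}"

        lines += [
            f"Accuracy (Acc):  {fmt(r.acc)}",
            f"Sensitivity:     {fmt(r.sn)}",
            f"Specificity:     {fmt(r.sp)}",
            f"F1 score:        {fmt(r.f1)}",
            f"MCC:             {fmt(r.mcc)}",
            f"AUC:             {fmt(r.auc)}",
            "=" * 64,
        ]
        return "\n".join(lines)
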