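"""Latent-variable risk model: interrelation matrix, NMF features, CV metrics.

The procedure: build a nonnegative matrix V whose columns encode the
interrelations between clinical flags (initial type 1 pattern, syncope,
atrial fibrillation) and min-max-scaled ECG variables (QRS duration, QTc);
factorize V ~ W H with d latent variables; append the columns of W to the
base risk variables (syncope, AF, QRS, QTc) in a logistic regression; and
score by stratified 2-fold cross-validation with precision, recall, F1
(macro over the two outcome classes at probability threshold 0.5) and AUC.

NMF is fit on the training fold only; held-out subjects are embedded by
projecting onto the frozen loadings, so no outcome or feature information
leaks across the fold boundary. (``joint_nmf=True`` reproduces the leaky
all-rows factorization for comparison.) d = 0 reduces exactly to the plain
logistic baseline.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._base import (
    BaseEstimator,
    DomainError,
    SchemaError,
    SeparationError,
    StratificationError,
    check_is_fitted,
)
from .association import fit_logistic
from .cohort import Cohort
from .nmf import LatentNMF, nmf_fit, nmf_project
from .roc import mann_whitney_auc

__all__ = [
    "InterrelationSpec",
    "CVReport",
    "LatentRiskModel",
    "build_interrelation_matrix",
    "augment_features",
    "cv_evaluate",
    "d_sweep",
    "stratified_folds",
    "classification_metrics",
]

logger = logging.getLogger(__name__)

DEFAULT_BASE_VARS = ("syncope", "af", "qrs_ms", "qtc_ms")
_CONTINUOUS_BASE = ("qrs_ms", "qtc_ms", "age_years", "qt_ms")


@dataclass(frozen=True)
class InterrelationSpec:
    """Which clinical and ECG variables form the interrelation matrix V.

    ``products`` mode (default): one column per (clinical, ECG) pair holding
    ``flag * scaled_ecg`` — 3 x 2 = 6 columns by default, matching the
    maximum swept d of 6. ``raw_features`` mode: the scaled variables side by
    side (5 columns by default).
    """

    clinical_vars: tuple[str, ...] = ("initial_type1", "syncope", "af")
    ecg_vars: tuple[str, ...] = ("qrs_ms", "qtc_ms")
    mode: str = "products"

    def __post_init__(self) -> None:
        if self.mode not in ("products", "raw_features"):
            raise DomainError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "clinical_vars", tuple(self.clinical_vars))
        object.__setattr__(self, "ecg_vars", tuple(self.ecg_vars))

    @property
    def n_columns(self) -> int:
        if self.mode == "products":
            return len(self.clinical_vars) * len(self.ecg_vars)
        return len(self.clinical_vars) + len(self.ecg_vars)

    def column_names(self) -> list[str]:
        if self.mode == "products":
            return [f"{c}*{e}" for c in self.clinical_vars for e in self.ecg_vars]
        return list(self.clinical_vars) + list(self.ecg_vars)


class _EcgScaler:
    """Min-max scaler fit on training rows; transform clips into [0, 1]."""

    def fit(self, X: np.ndarray) -> "_EcgScaler":
        X = np.asarray(X, dtype=float)
        self.mins_ = X.min(axis=0)
        self.spans_ = X.max(axis=0) - self.mins_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros_like(X)
        nz = self.spans_ > 0
        out[:, nz] = (X[:, nz] - self.mins_[nz]) / self.spans_[nz]
        return np.clip(out, 0.0, 1.0)


def _frame_of(cohort) -> pd.DataFrame:
    return cohort.to_frame() if isinstance(cohort, Cohort) else pd.DataFrame(cohort)


def build_interrelation_matrix(
    cohort,
    spec: InterrelationSpec = InterrelationSpec(),
    scaler: Optional[_EcgScaler] = None,
) -> np.ndarray:
    """Patients x interrelation-columns nonnegative matrix in [0, 1].

    ECG variables are min-max scaled (fit here, or with a supplied
    pre-fitted ``scaler`` for held-out data); clinical flags enter as 0/1.
    """
    df = _frame_of(cohort)
    missing = [v for v in (*spec.clinical_vars, *spec.ecg_vars) if v not in df.columns]
    if missing:
        raise SchemaError(f"missing variable(s) for interrelation matrix: {missing}")
    cols = list(spec.clinical_vars) + list(spec.ecg_vars)
    complete = df[cols].notna().all(axis=1)
    if not complete.all():
        logger.info(
            "build_interrelation_matrix: excluding %d records with missing values",
            int((~complete).sum()),
        )
        df = df[complete]
    clin = df[list(spec.clinical_vars)].to_numpy(dtype=float)
    ecg_raw = df[list(spec.ecg_vars)].to_numpy(dtype=float)
    if scaler is None:
        scaler = _EcgScaler().fit(ecg_raw)
    ecg = scaler.transform(ecg_raw)
    if spec.mode == "raw_features":
        return np.hstack([clin, ecg])
    n = len(df)
    V = np.empty((n, spec.n_columns))
    k = 0
    for i in range(clin.shape[1]):
        for j in range(ecg.shape[1]):
            V[:, k] = clin[:, i] * ecg[:, j]
            k += 1
    return V


def augment_features(
    cohort,
    W: Optional[np.ndarray],
    base_vars: Sequence[str] = DEFAULT_BASE_VARS,
    standardize_stats: Optional[dict] = None,
    latent_stats: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> np.ndarray:
    """Design matrix [intercept | base variables | d latent columns].

    Continuous base variables and the latent columns are standardized
    (mean 0, sd 1) for numeric stability — the NMF scale indeterminacy makes
    the raw latent scale arbitrary, and standardization is an affine
    reparametrization that leaves the fitted probabilities unchanged. With
    ``standardize_stats`` / ``latent_stats`` supplied, training-fold
    statistics are applied (for held-out data). ``W=None`` (or zero columns)
    returns the baseline design.
    """
    df = _frame_of(cohort)
    n = len(df)
    cols = [np.ones(n)]
    for var in base_vars:
        if var not in df.columns:
            raise SchemaError(f"missing base variable {var!r}")
        x = df[var].to_numpy(dtype=float)
        if var in _CONTINUOUS_BASE:
            if standardize_stats is not None and var in standardize_stats:
                mean, sd = standardize_stats[var]
            else:
                mean, sd = x.mean(), x.std()
            x = (x - mean) / (sd if sd > 0 else 1.0)
        cols.append(x)
    design = np.column_stack(cols)
    if W is not None and np.size(W):
        W = np.asarray(W, dtype=float)
        if W.shape[0] != n:
            raise DomainError(
                f"latent matrix has {W.shape[0]} rows for a cohort of {n}"
            )
        if latent_stats is None:
            means = W.mean(axis=0)
            sds = W.std(axis=0)
        else:
            means, sds = latent_stats
        sds = np.where(sds > 0, sds, 1.0)
        design = np.hstack([design, (W - means) / sds])
    return design


def standardize_stats_for(df: pd.DataFrame, base_vars: Sequence[str]) -> dict:
    stats = {}
    for var in base_vars:
        if var in _CONTINUOUS_BASE:
            x = df[var].to_numpy(dtype=float)
            stats[var] = (float(x.mean()), float(x.std()))
    return stats


def stratified_folds(y, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment (0..n_folds-1 per subject), stratified by class.

    Within each class, indices are shuffled and dealt round-robin, so every
    fold contains both classes whenever each class has >= n_folds members.
    """
    y = np.asarray(y).astype(int).ravel()
    rng = np.random.default_rng(int(seed % (2**31)))
    assignment = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < n_folds:
            raise StratificationError(
                f"class {cls} has {idx.size} members, fewer than {n_folds} folds"
            )
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % n_folds
    return assignment


def classification_metrics(
    y_true, y_pred, averaging: str = "macro"
) -> tuple[float, float, float]:
    """(precision, recall, F1) with macro / weighted / positive_class averaging.

    Per class, F1 is the harmonic mean of that class's precision and recall;
    undefined ratios (empty denominator) count as 0.
    """
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    per_class = {}
    for cls in (0, 1):
        tp = int(((y_pred == cls) & (y_true == cls)).sum())
        fp = int(((y_pred == cls) & (y_true != cls)).sum())
        fn = int(((y_pred != cls) & (y_true == cls)).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[cls] = (prec, rec, f1, int((y_true == cls).sum()))
    if averaging == "positive_class":
        p, r, f, _ = per_class[1]
        return p, r, f
    if averaging == "macro":
        vals = [np.mean([per_class[c][i] for c in (0, 1)]) for i in range(3)]
        return tuple(float(v) for v in vals)
    if averaging == "weighted":
        n = y_true.size
        vals = [
            sum(per_class[c][i] * per_class[c][3] / n for c in (0, 1))
            for i in range(3)
        ]
        return tuple(float(v) for v in vals)
    raise DomainError(f"unknown averaging {averaging!r}")


@dataclass(frozen=True)
class CVReport:
    """Cross-validated performance for one latent dimension d."""

    d: int
    per_fold: tuple[dict, ...]
    precision: float
    recall: float
    f1: float
    auc: float
    n_folds: int
    seed: int
    averaging: str
    fold_assignment: tuple[int, ...] = ()

    @property
    def fold_hash(self) -> str:
        """Stable digest of the fold membership, for pairing checks."""
        return hashlib.sha256(
            np.asarray(self.fold_assignment, dtype=np.int64).tobytes()
        ).hexdigest()


class LatentRiskModel(BaseEstimator):
    """NMF-augmented logistic risk classifier over a cohort frame.

    ``fit(df, y)`` builds the interrelation matrix from ``df`` (a cohort
    DataFrame with the canonical columns), extracts ``d`` nonnegative latent
    variables, and fits an IRLS logistic regression on
    [base risk variables | latent columns]. ``predict_proba(df)`` embeds new
    subjects by projection onto the frozen NMF loadings. ``d=0`` is the plain
    logistic baseline (no NMF at all).
    """

    def __init__(
        self,
        d: int = 4,
        spec: InterrelationSpec = InterrelationSpec(),
        base_vars: Sequence[str] = DEFAULT_BASE_VARS,
        nmf_max_iter: int = 300,
        nmf_tol: float = 1e-6,
        nmf_restarts: int = 3,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.d = d
        self.spec = spec
        self.base_vars = base_vars
        self.nmf_max_iter = nmf_max_iter
        self.nmf_tol = nmf_tol
        self.nmf_restarts = nmf_restarts
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, df, y) -> "LatentRiskModel":
        df = _frame_of(df)
        y = np.asarray(y).astype(int).ravel()
        self.scaler_ = _EcgScaler().fit(
            df[list(self.spec.ecg_vars)].to_numpy(dtype=float)
        )
        self.standardize_stats_ = standardize_stats_for(df, self.base_vars)
        if self.d > 0:
            V = build_interrelation_matrix(df, self.spec, scaler=self.scaler_)
            self.nmf_ = LatentNMF(
                n_components=self.d,
                max_iter=self.nmf_max_iter,
                tol=self.nmf_tol,
                n_restarts=self.nmf_restarts,
                random_state=self.random_state,
            ).fit(V)
            W = self.nmf_.embedding_
            self.latent_stats_ = (W.mean(axis=0), W.std(axis=0))
        else:
            self.nmf_ = None
            self.latent_stats_ = None
            W = None
        design = augment_features(
            df,
            W,
            self.base_vars,
            standardize_stats=self.standardize_stats_,
            latent_stats=self.latent_stats_,
        )
        fit = fit_logistic(design, y)
        self.coef_ = fit.coef
        self.cov_ = fit.cov
        self.converged_ = fit.converged
        self.classes_ = np.array([0, 1])
        return self

    def _design(self, df) -> np.ndarray:
        df = _frame_of(df)
        if self.d > 0:
            V = build_interrelation_matrix(df, self.spec, scaler=self.scaler_)
            W = self.nmf_.transform(V)
        else:
            W = None
        return augment_features(
            df,
            W,
            self.base_vars,
            standardize_stats=self.standardize_stats_,
            latent_stats=self.latent_stats_,
        )

    def decision_function(self, df) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self._design(df) @ self.coef_

    def predict_proba(self, df) -> np.ndarray:
        eta = self.decision_function(df)
        p1 = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, df) -> np.ndarray:
        return (self.predict_proba(df)[:, 1] >= self.threshold).astype(int)


def cv_evaluate(
    cohort,
    spec: InterrelationSpec = InterrelationSpec(),
    d: int = 0,
    n_folds: int = 2,
    seed: int = 0,
    averaging: str = "macro",
    base_vars: Sequence[str] = DEFAULT_BASE_VARS,
    threshold: float = 0.5,
    nmf_max_iter: int = 300,
    nmf_tol: float = 1e-6,
    nmf_restarts: int = 3,
    joint_nmf: bool = False,
    folds: Optional[np.ndarray] = None,
) -> CVReport:
    """Stratified k-fold CV of the d-latent-variable risk model.

    Per fold: min-max scaling, NMF loadings, and standardization statistics
    come from the training rows only; held-out rows are embedded by
    projection. Precision/recall/F1 are computed at ``threshold`` with the
    configured class ``averaging``; AUC is threshold-free (Mann-Whitney).
    Folds hitting separation are flagged and excluded from the means with a
    warning.
    """
    df = _frame_of(cohort)
    y = df["vtvf"].to_numpy(dtype=int)
    if folds is None:
        folds = stratified_folds(y, n_folds, seed)
    folds = np.asarray(folds, dtype=int)

    joint_W = None
    if joint_nmf and d > 0:
        V_all = build_interrelation_matrix(df, spec)
        joint_W = nmf_fit(
            V_all, d, max_iter=nmf_max_iter, tol=nmf_tol,
            n_restarts=nmf_restarts, seed=seed,
        ).W

    per_fold = []
    for k in range(n_folds):
        test_mask = folds == k
        train_df = df[~test_mask].reset_index(drop=True)
        test_df = df[test_mask].reset_index(drop=True)
        y_train = y[~test_mask]
        y_test = y[test_mask]
        if y_test.sum() == 0 or y_train.sum() == 0:
            raise StratificationError(f"fold {k} lacks positive outcomes")

        try:
            if joint_nmf and d > 0:
                scaler = _EcgScaler().fit(
                    train_df[list(spec.ecg_vars)].to_numpy(dtype=float)
                )
                stats_ = standardize_stats_for(train_df, base_vars)
                W_train = joint_W[~test_mask]
                lat_stats = (W_train.mean(axis=0), W_train.std(axis=0))
                design_train = augment_features(
                    train_df, W_train, base_vars, stats_, lat_stats
                )
                fit = fit_logistic(design_train, y_train)
                design_test = augment_features(
                    test_df, joint_W[test_mask], base_vars, stats_, lat_stats
                )
                eta = design_test @ fit.coef
            else:
                model = LatentRiskModel(
                    d=d,
                    spec=spec,
                    base_vars=base_vars,
                    nmf_max_iter=nmf_max_iter,
                    nmf_tol=nmf_tol,
                    nmf_restarts=nmf_restarts,
                    threshold=threshold,
                    random_state=seed,
                ).fit(train_df, y_train)
                eta = model.decision_function(test_df)
        except SeparationError as exc:
            warnings.warn(
                f"fold {k} excluded from CV means: {exc}", stacklevel=2
            )
            per_fold.append({"fold": k, "error": str(exc)})
            continue

        prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        y_pred = (prob >= threshold).astype(int)
        prec, rec, f1 = classification_metrics(y_test, y_pred, averaging)
        auc = mann_whitney_auc(prob, y_test)
        per_fold.append(
            {
                "fold": k,
                "precision": prec,
                "recall": rec,
                "f1": f1,
                "auc": auc,
                "n_test": int(test_mask.sum()),
            }
        )

    ok = [f for f in per_fold if "error" not in f]
    if not ok:
        raise SeparationError("every fold failed with separation")
    mean = lambda key: float(np.mean([f[key] for f in ok]))
    return CVReport(
        d=d,
        per_fold=tuple(per_fold),
        precision=mean("precision"),
        recall=mean("recall"),
        f1=mean("f1"),
        auc=mean("auc"),
        n_folds=n_folds,
        seed=seed,
        averaging=averaging,
        fold_assignment=tuple(int(v) for v in folds),
    )


def d_sweep(
    cohort,
    spec: InterrelationSpec = InterrelationSpec(),
    d_values: Sequence[int] = (0, 2, 3, 4, 5, 6),
    n_folds: int = 2,
    seed: int = 0,
    **kwargs,
) -> list[CVReport]:
    """One CVReport per latent dimension, with a shared fold assignment.

    Sharing folds across d makes the sweep a paired comparison: metric
    differences between d values are not confounded by the split.
    """
    df = _frame_of(cohort)
    y = df["vtvf"].to_numpy(dtype=int)
    folds = stratified_folds(y, n_folds, seed)
    return [
        cv_evaluate(
            df,
            spec=spec,
            d=d,
            n_folds=n_folds,
            seed=seed,
            folds=folds,
            **kwargs,
        )
        for d in d_values
    ]


def format_sweep(reports: Sequence[CVReport]) -> str:
    """TSV grid: one row per d with precision, recall, F1, AUC."""
    lines = ["d\tprecision\trecall\tf1\tauc"]
    for r in reports:
        lines.append(
            f"{r.d}\t{r.precision:.4f}\t{r.recall:.4f}\t{r.f1:.4f}\t{r.auc:.4f}"
        )
    return "\n".join(lines) + "\n"
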