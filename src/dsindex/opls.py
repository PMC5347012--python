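"""Orthogonal projections to latent structures (OPLS) for two-class discrimination.

The model splits predictor variation into a single predictive component,
correlated with the coded class response, and ``n_orth`` orthogonal
components that carry systematic variation unrelated to class (for
example within-class anatomy).  Orthogonal components are estimated and
removed by deflation before the predictive component is fitted, so the
predicted response of a subject is invariant to any variation lying
along the stored orthogonal loadings.

Fitting is closed-form per component (single-response NIPALS needs no
iteration):

    repeat n_orth times on the current X:
        w* = X'y / ||X'y||          candidate predictive weight
        t* = X w*                   candidate score
        p* = X't* / (t*'t*)         candidate loading
        w_o ∝ p* - (w*'p*) w*       orthogonal weight (unit norm)
        t_o = X w_o,  p_o = X't_o / (t_o't_o)
        X ← X - t_o p_o'            deflate
    then on the deflated X:
        w = X'y / ||X'y||,  t = X w,  p = X't/(t't),  c = y't/(t't)

with y the coded labels (control=0, disease=1) centered by the training
mean.  Prediction for a new row x removes the stored orthogonal
variation sequentially (t_o = x'w_o; x ← x - t_o p_o) and returns
``c·(x'w) + y_mean``, so an index near 1 is disease-like and near 0
control-like.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io import FeatureMatrix
from .preprocess import (ScalingParams, preprocess_apply, preprocess_fit)
from .schema import ROISchema

_EPS = 1e-12

MODEL_FILE_VERSION = 1


class DegenerateLabelError(ValueError):
    """y contains a single class; a discriminant model is undefined."""


class NoCovarianceError(ValueError):
    """X'y is numerically zero; no predictive direction exists."""


@dataclass
class OplsModel:
    """Fitted OPLS discriminant model (weights in standardized space).

    ``scaling`` carries the preprocessing chain estimated on the
    training set; it is absent (None) for models fitted directly on a
    pre-standardized matrix.
    """

    w: np.ndarray                     # unit predictive weight
    p: np.ndarray                     # predictive loading
    c: float                          # scalar y-loading
    y_mean: float                     # intercept on the coded-y scale
    W_orth: np.ndarray                # (n_orth, p) orthogonal weights, unit norm
    P_orth: np.ndarray                # (n_orth, p) orthogonal loadings
    n_orth: int
    y_coding: dict[str, int] = field(default_factory=dict)
    scaling: ScalingParams | None = None
    schema_fingerprint: str = ""
    train_ids: list[str] = field(default_factory=list)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Predictive scores t after removing stored orthogonal variation."""
        X = np.atleast_2d(np.asarray(X, float)).copy()
        for w_o, p_o in zip(self.W_orth, self.P_orth):
            t_o = X @ w_o
            X -= np.outer(t_o, p_o)
        return X @ self.w

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted coded response (severity index) per row of X."""
        return self.c * self.transform(X) + self.y_mean

    def to_dict(self) -> dict:
        return {
            "version": MODEL_FILE_VERSION,
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "c": self.c,
            "y_mean": self.y_mean,
            "W_orth": self.W_orth.tolist(),
            "P_orth": self.P_orth.tolist(),
            "n_orth": self.n_orth,
            "y_coding": self.y_coding,
            "scaling": None if self.scaling is None else self.scaling.to_dict(),
            "schema_fingerprint": self.schema_fingerprint,
            "train_ids": self.train_ids,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "OplsModel":
        if d.get("version") != MODEL_FILE_VERSION:
            raise ValueError(f"unsupported model file version {d.get('version')!r}")
        p = len(d["w"])
        return cls(
            w=np.asarray(d["w"], float),
            p=np.asarray(d["p"], float),
            c=float(d["c"]),
            y_mean=float(d["y_mean"]),
            W_orth=np.asarray(d["W_orth"], float).reshape(d["n_orth"], p),
            P_orth=np.asarray(d["P_orth"], float).reshape(d["n_orth"], p),
            n_orth=int(d["n_orth"]),
            y_coding={k: int(v) for k, v in d["y_coding"].items()},
            scaling=None if d["scaling"] is None else ScalingParams.from_dict(d["scaling"]),
            schema_fingerprint=d["schema_fingerprint"],
            train_ids=list(d["train_ids"]),
        )

    @classmethod
    def load(cls, path) -> "OplsModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CvResult:
    """Cross-validation summary for an OPLS discriminant model."""

    q2: float
    y_pred_cv: np.ndarray      # per-subject prediction, each subject held out once
    fold_assignment: np.ndarray
    sensitivity: float
    specificity: float
    n_orth: int
    press: float = np.nan
    ss: float = np.nan


def fit_opls(X: np.ndarray, y: np.ndarray, n_orth: int = 0) -> OplsModel:
    """Fit the OPLS discriminant model on a standardized matrix.

    ``y`` is the coded class vector in {0, 1}.  The response is centered
    internally; predictions are returned on the original coded scale.
    """
    X = np.asarray(X, float).copy()
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of subjects")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateLabelError("y contains a single class")
    if n_orth < 0:
        raise ValueError("n_orth must be non-negative")
    if X.shape[0] < n_orth + 2:
        raise ValueError("need at least n_orth + 2 subjects")
    y_mean = float(y.mean())
    yc = y - y_mean

    W_orth, P_orth = [], []
    for _ in range(n_orth):
        w_star = X.T @ yc
        nrm = np.linalg.norm(w_star)
        if nrm < _EPS:
            raise NoCovarianceError("X'y is numerically zero")
        w_star /= nrm
        t_star = X @ w_star
        p_star = X.T @ t_star / (t_star @ t_star)
        w_o = p_star - (w_star @ p_star) * w_star
        nrm_o = np.linalg.norm(w_o)
        if nrm_o < _EPS:
            # no systematic variation left outside the predictive direction
            break
        w_o /= nrm_o
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X -= np.outer(t_o, p_o)
        W_orth.append(w_o)
        P_orth.append(p_o)

    w = X.T @ yc
    nrm = np.linalg.norm(w)
    if nrm < _EPS:
        raise NoCovarianceError("X'y is numerically zero after deflation")
    w /= nrm
    t = X @ w
    p = X.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))

    k = len(W_orth)
    nfeat = X.shape[1]
    return OplsModel(
        w=w, p=p, c=c, y_mean=y_mean,
        W_orth=np.asarray(W_orth, float).reshape(k, nfeat),
        P_orth=np.asarray(P_orth, float).reshape(k, nfeat),
        n_orth=k,
    )


def project(model: OplsModel, X_new) -> np.ndarray:
    """Severity index for each row of an already-standardized matrix.

    For a matrix produced by the model's own preprocessing chain this
    reproduces the training fitted values exactly on training rows.
    """
    if isinstance(X_new, FeatureMatrix):
        if list(X_new.columns) != _model_columns(model):
            raise ValueError("feature matrix columns do not align with model")
        X_new = X_new.values
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"matrix has {X_new.shape[1]} columns, model expects {model.w.shape[0]}"
        )
    return model.predict(X_new)


def _model_columns(model: OplsModel) -> list[str] | None:
    return None if model.scaling is None else list(model.scaling.columns)


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    y = np.asarray(y)
    for cls in np.unique(y):
        if (y == cls).sum() < k:
            raise ValueError(
                f"class {cls!r} has fewer than {k} members; stratified "
                f"{k}-fold split impossible"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = f
    return assignment


def cross_validate(features: FeatureMatrix, y: np.ndarray, schema: ROISchema,
                   k: int = 7, n_orth: int = 0, seed: int = 0,
                   icv_mode: str = "residualize") -> CvResult:
    """Stratified k-fold cross-validation with per-fold preprocessing.

    Inside each fold the whole chain — ICV adjustment, standardization,
    OPLS fit — is re-estimated on the training folds only, and the
    held-out fold is transformed with the stored parameters before
    projection.  Q2 = 1 - PRESS/SS with SS about the overall class mean;
    sensitivity and specificity come from the cross-validated
    predictions thresholded at 0.5 (disease class positive).
    """
    y = np.asarray(y, float).ravel()
    if k < 2:
        raise ValueError("k must be at least 2")
    assignment = _stratified_folds(y, k, seed)
    y_pred = np.full(len(y), np.nan)
    for f in range(k):
        train = assignment != f
        Z_tr, params = preprocess_fit(
            _rows(features, train), schema, icv_mode=icv_mode)
        model = fit_opls(Z_tr.values, y[train], n_orth=n_orth)
        Z_te = preprocess_apply(_rows(features, ~train), schema, params)
        y_pred[~train] = model.predict(Z_te.values)
    press = float(np.sum((y - y_pred) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / ss
    pos, neg = y == 1, y == 0
    sens = float(np.mean(y_pred[pos] >= 0.5)) if pos.any() else np.nan
    spec = float(np.mean(y_pred[neg] < 0.5)) if neg.any() else np.nan
    return CvResult(q2=q2, y_pred_cv=y_pred, fold_assignment=assignment,
                    sensitivity=sens, specificity=spec, n_orth=n_orth,
                    press=press, ss=ss)


def _rows(features: FeatureMatrix, mask: np.ndarray) -> FeatureMatrix:
    icv = None if features.icv is None else features.icv[mask]
    return FeatureMatrix(features.values[mask],
                         [r for r, m in zip(features.row_ids, mask) if m],
                         list(features.columns), icv)


def select_orthogonal_components(features: FeatureMatrix, y: np.ndarray,
                                 schema: ROISchema, k: int = 7, seed: int = 0,
                                 max_orth: int = 5, min_gain: float = 0.01,
                                 icv_mode: str = "residualize") -> int:
    """Smallest component count beyond which cross-validated Q2 stops improving.

    Returns the least n with Q2(n+1) - Q2(n) < ``min_gain``, capped at
    ``max_orth``.  Deterministic for a fixed seed (the same fold split
    is reused at every n).
    """
    if max_orth <= 0:
        return 0
    q_prev = cross_validate(features, y, schema, k=k, n_orth=0, seed=seed,
                            icv_mode=icv_mode).q2
    for n in range(max_orth):
        q_next = cross_validate(features, y, schema, k=k, n_orth=n + 1,
                                seed=seed, icv_mode=icv_mode).q2
        if q_next - q_prev < min_gain:
            return n
        q_prev = q_next
    return max_orth


def variable_importance(model: OplsModel, X_train: np.ndarray,
                        top_k: int = 25) -> list[tuple[str | int, float, float]]:
    """Rank features by |covariance| with the predictive score.

    Covariance and correlation are computed between each column of the
    orthogonality-filtered training matrix and the predictive score t,
    oriented so that a positive value means the measure is larger in
    the control class (atrophied regions rank positive, enlarged
    ventricles negative).
    """
    X = np.atleast_2d(np.asarray(X_train, float)).copy()
    for w_o, p_o in zip(model.W_orth, model.P_orth):
        t_o = X @ w_o
        X -= np.outer(t_o, p_o)
    t = X @ model.w
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    tc = t - t.mean()
    cov = Xc.T @ tc / (n - 1)
    sd_x = Xc.std(axis=0, ddof=1)
    sd_t = tc.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(sd_x > 0, cov / (sd_x * sd_t), 0.0)
    # orient: control-high measures positive (index increases with disease)
    s = -np.sign(model.c) if model.c != 0 else -1.0
    cov, corr = s * cov, s * corr
    names = _model_columns(model) or list(range(X.shape[1]))
    order = np.argsort(-np.abs(cov))[:top_k]
    return [(names[j], float(cov[j]), float(corr[j])) for j in order]
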