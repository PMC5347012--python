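"""ICV adjustment and column standardization with strict train/apply separation.

Every statistic used to transform a projected (unseen) subject is
estimated on the training rows only and stored in :class:`ScalingParams`,
so cross-validation and projection are leakage-free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureMatrix
from .schema import ROISchema

ICV_MODES = ("residualize", "append", "none")

ICV_COLUMN = "__icv__"


class DegenerateCovariateError(ValueError):
    """ICV has no variance on the training rows; residualization undefined."""


class AlignmentError(ValueError):
    """Stored parameters do not match the matrix they are applied to."""


@dataclass
class ScalingParams:
    """Per-column centering/scaling constants plus ICV regression coefficients.

    ``icv_coef`` maps each adjusted volume column to its (intercept, slope)
    straight-line fit on ICV, estimated on training rows.  ``dropped``
    lists columns excluded for zero training variance; they are removed
    from every transformed matrix.
    """

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray
    dropped: list[str] = field(default_factory=list)
    icv_mode: str = "none"
    icv_coef: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "dropped": self.dropped,
            "icv_mode": self.icv_mode,
            "icv_coef": {k: list(v) for k, v in self.icv_coef.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            columns=list(d["columns"]),
            mean=np.asarray(d["mean"], float),
            sd=np.asarray(d["sd"], float),
            dropped=list(d["dropped"]),
            icv_mode=d["icv_mode"],
            icv_coef={k: (float(a), float(b)) for k, (a, b) in d["icv_coef"].items()},
        )


def adjust_icv(features: FeatureMatrix, schema: ROISchema, mode: str = "residualize",
               train_mask: np.ndarray | None = None,
               coef: dict[str, tuple[float, float]] | None = None,
               ) -> tuple[FeatureMatrix, dict[str, tuple[float, float]]]:
    """Remove (or append) the total-intracranial-volume nuisance signal.

    residualize
        Each volume-kind column is replaced by its residual from a
        straight line on ICV fitted on ``train_mask`` rows and applied
        to all rows.  Thickness columns are untouched.
    append
        ICV is appended as one extra column (standardized later with
        the rest), leaving features unchanged.
    none
        Identity.

    When ``coef`` is given (apply mode), the stored line is used without
    re-estimation and ``train_mask`` is ignored.
    """
    if mode not in ICV_MODES:
        raise ValueError(f"unknown icv mode {mode!r}")
    if mode == "none":
        return features.copy(), {}
    if features.icv is None:
        raise ValueError("feature matrix carries no ICV values")
    icv = np.asarray(features.icv, float)
    out = features.copy()

    if mode == "append":
        vals = np.hstack([out.values, icv[:, None]])
        return FeatureMatrix(vals, out.row_ids, out.columns + [ICV_COLUMN], icv), {}

    vol_cols = [e.name for e in schema if e.kind == "volume" and e.name in out.columns]
    if coef is None:
        if train_mask is None:
            train_mask = np.ones(len(icv), bool)
        train_mask = np.asarray(train_mask, bool)
        if not train_mask.any():
            raise ValueError("residualize requires a non-empty training mask")
        icv_tr = icv[train_mask]
        if np.ptp(icv_tr) == 0:
            raise DegenerateCovariateError("ICV constant on training rows")
        coef = {}
        x = icv_tr - icv_tr.mean()
        denom = float(x @ x)
        for name in vol_cols:
            j = out.columns.index(name)
            ytr = out.values[train_mask, j]
            slope = float(x @ (ytr - ytr.mean())) / denom
            intercept = float(ytr.mean() - slope * icv_tr.mean())
            coef[name] = (intercept, slope)
    for name, (a, b) in coef.items():
        if name not in out.columns:
            raise AlignmentError(f"stored ICV coefficient for unknown column {name!r}")
        j = out.columns.index(name)
        out.values[:, j] = out.values[:, j] - (a + b * icv)
    return out, coef


def standardize(features: FeatureMatrix, params: ScalingParams | None = None,
                train_mask: np.ndarray | None = None,
                ddof: int = 1) -> tuple[FeatureMatrix, ScalingParams]:
    """Center and scale columns to unit variance (estimated on training rows).

    With ``params`` given, applies the stored transform exactly; columns
    recorded as dropped are removed.  Otherwise estimates per-column
    mean and sd (n-1 denominator) on ``train_mask`` rows, drops
    zero-variance columns, and transforms all rows.
    """
    X = features.values
    if params is None:
        if train_mask is None:
            train_mask = np.ones(X.shape[0], bool)
        train_mask = np.asarray(train_mask, bool)
        if not train_mask.any():
            raise ValueError("standardize requires a non-empty training mask")
        mu = X[train_mask].mean(axis=0)
        sd = X[train_mask].std(axis=0, ddof=ddof)
        keep = sd > 0
        dropped = [c for c, k in zip(features.columns, keep) if not k]
        params = ScalingParams(
            columns=[c for c, k in zip(features.columns, keep) if k],
            mean=mu[keep], sd=sd[keep], dropped=dropped,
        )
    if set(params.columns) - set(features.columns):
        raise AlignmentError("stored scaling refers to columns absent from matrix")
    idx = [features.columns.index(c) for c in params.columns]
    Z = (X[:, idx] - params.mean) / params.sd
    out = FeatureMatrix(Z, list(features.row_ids), list(params.columns),
                        None if features.icv is None else features.icv.copy())
    return out, params


def preprocess_fit(features: FeatureMatrix, schema: ROISchema,
                   icv_mode: str = "residualize",
                   train_mask: np.ndarray | None = None,
                   ) -> tuple[FeatureMatrix, ScalingParams]:
    """Estimate the full preprocessing chain (ICV then scaling) on training rows."""
    adj, coef = adjust_icv(features, schema, mode=icv_mode, train_mask=train_mask)
    out, params = standardize(adj, train_mask=train_mask)
    params.icv_mode = icv_mode
    params.icv_coef = coef
    return out, params


def preprocess_apply(features: FeatureMatrix, schema: ROISchema,
                     params: ScalingParams) -> FeatureMatrix:
    """Apply a stored preprocessing chain to new rows without re-estimation."""
    coef = params.icv_coef if params.icv_mode == "residualize" else None
    adj, _ = adjust_icv(features, schema, mode=params.icv_mode, coef=coef)
    out, _ = standardize(adj, params=params)
    return out
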