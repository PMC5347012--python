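"""Severity indices and AD-like / HC-like subtype calls for projected subjects.

A subject's disease severity index is the OPLS-predicted coded response
after the model's stored preprocessing chain is applied: values near 1
are disease-like, near 0 control-like, and they are deliberately not
clipped to [0, 1].  Subtyping thresholds the index at a cutoff (default
0.5, ties to AD-like).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import CohortTable, build_feature_matrix
from .opls import OplsModel, project
from .preprocess import preprocess_apply
from .schema import ROISchema


class LeakageError(ValueError):
    """Target subjects overlap the model's training set."""


@dataclass(frozen=True)
class IndexResult:
    """Severity index for one subject, optionally with a subtype call."""

    subject_id: str
    index: float
    subtype: str | None = None       # "AD-like" | "HC-like"
    cutoff: float | None = None
    model_fingerprint: str = ""


def compute_index(model: OplsModel, cohort: CohortTable, schema: ROISchema,
                  target_group: str, allow_train_overlap: bool = False,
                  ) -> list[IndexResult]:
    """Project one cohort group onto a fitted model as unseen data.

    Applies the model's stored ICV adjustment and scaling, then the
    OPLS projection; results preserve cohort order.  Refuses subjects
    that were in the training set unless ``allow_train_overlap`` is set
    (useful for training-set diagnostics).
    """
    sel = cohort.data[cohort.data["group"] == target_group]
    if sel.empty:
        return []
    ids = sel["subject_id"].astype(str).tolist()
    overlap = set(ids) & set(model.train_ids)
    if overlap and not allow_train_overlap:
        raise LeakageError(
            f"{len(overlap)} target subjects were used to train the model "
            f"(e.g. {sorted(overlap)[:3]}); pass allow_train_overlap to override")
    if model.scaling is None:
        raise ValueError("model carries no preprocessing parameters")
    feats = build_feature_matrix(CohortTable(sel.reset_index(drop=True), schema),
                                 schema, {target_group})
    Z = preprocess_apply(feats, schema, model.scaling)
    idx = project(model, Z.values)
    fp = model.schema_fingerprint
    return [IndexResult(subject_id=i, index=float(v), model_fingerprint=fp)
            for i, v in zip(ids, idx)]


def classify(results: list[IndexResult], cutoff: float = 0.5) -> list[IndexResult]:
    """Assign subtypes: AD-like iff index >= cutoff (tie goes to AD-like)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    out = []
    for r in results:
        if not np.isfinite(r.index):
            raise ValueError(f"non-finite index for subject {r.subject_id!r}")
        subtype = "AD-like" if r.index >= cutoff else "HC-like"
        out.append(replace(r, subtype=subtype, cutoff=cutoff))
    return out


def results_to_frame(results: list[IndexResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {"subject_id": [r.subject_id for r in results],
         "index": [r.index for r in results],
         "subtype": [r.subtype for r in results]})


def subtype_counts(results: list[IndexResult]) -> dict[str, int]:
    counts = {"AD-like": 0, "HC-like": 0}
    for r in results:
        if r.subtype is not None:
            counts[r.subtype] += 1
    return counts
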