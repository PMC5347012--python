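"""End-to-end orchestration: simulate → fit → project → classify → validate.

One :class:`RunConfig` plus one seed reproduces a whole run; sub-seeds
for simulation and fold assignment are derived deterministically from
the master seed, and every artifact records the configuration in
effect.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import outcomes as oc
from .index import classify, compute_index, results_to_frame, subtype_counts
from .io import (CohortTable, build_feature_matrix, read_cohort_table,
                 read_followup_table, write_cohort_table, write_followup_table)
from .opls import (CvResult, OplsModel, cross_validate, fit_opls,
                   select_orthogonal_components, variable_importance)
from .preprocess import preprocess_fit
from .schema import ROISchema, default_schema
from .simulate import SimulationConfig, generate_cohort, generate_followup


class StageError(RuntimeError):
    """Failure annotated with the pipeline stage it occurred in."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Settings for one reproducible pipeline run."""

    out_dir: str = "results"
    cohort_path: str | None = None       # None → simulate
    followup_path: str | None = None
    disease: str = "AD"
    control: str = "HC"
    target_group: str = "SMD"
    folds: int = 7
    n_orth: int | str = "auto"           # integer or "auto"
    max_orth: int = 5
    cutoff: float = 0.5
    icv_mode: str = "residualize"
    bh_q: float = 0.05
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # output location is not part of the analysis
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _subseed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def fit_severity_model(cohort: CohortTable, schema: ROISchema,
                       disease: str = "AD", control: str = "HC",
                       folds: int = 7, n_orth: int | str = "auto",
                       max_orth: int = 5, seed: int = 0,
                       icv_mode: str = "residualize",
                       ) -> tuple[OplsModel, CvResult]:
    """Train the discriminant model on two groups and cross-validate it.

    The returned model carries the preprocessing chain estimated on the
    full training set and is ready to project unseen subjects; the
    CvResult reports leakage-free Q2, sensitivity and specificity from
    the stratified k-fold scheme.
    """
    feats = build_feature_matrix(cohort, schema, {disease, control})
    sel = cohort.data[cohort.data["group"].isin({disease, control})]
    y = (sel["group"] == disease).to_numpy(float)
    if n_orth == "auto":
        n_orth = select_orthogonal_components(
            feats, y, schema, k=folds, seed=seed, max_orth=max_orth,
            icv_mode=icv_mode)
    cv = cross_validate(feats, y, schema, k=folds, n_orth=int(n_orth),
                        seed=seed, icv_mode=icv_mode)
    Z, params = preprocess_fit(feats, schema, icv_mode=icv_mode)
    model = fit_opls(Z.values, y, n_orth=int(n_orth))
    model.scaling = params
    model.y_coding = {control: 0, disease: 1}
    model.schema_fingerprint = schema.fingerprint()
    model.train_ids = list(feats.row_ids)
    return model, cv


def validate_subtypes(followup: pd.DataFrame, cohort: CohortTable,
                      index_frame: pd.DataFrame, bh_q: float = 0.05) -> dict:
    """Outcome table, progression stats, survival and log-rank for subtypes."""
    groups: dict[str, str] = {}
    subtype_by_id = dict(zip(index_frame["subject_id"].astype(str),
                             index_frame["subtype"]))
    for _, row in cohort.data.iterrows():
        sid = str(row["subject_id"])
        g = row["group"]
        if g == "SMD" and sid in subtype_by_id:
            groups[sid] = f"{subtype_by_id[sid]} SMD"
        else:
            groups[sid] = g
    present = followup["subject_id"].astype(str).isin(groups)
    counts = oc.outcome_table(followup[present], groups)

    report: dict = {"outcome_table": counts.to_dict(),
                    "groups_present": sorted(set(groups.values()))}
    outs = oc.subject_outcomes(followup[present])
    by_group: dict[str, list] = {}
    for o in outs:
        by_group.setdefault(groups[o.subject_id], []).append(o)

    def ev(g):
        return oc.events_from_outcomes(by_group.get(g, []))

    pvals, contrasts = [], []
    if "AD-like SMD" in by_group:
        for ref in ("HC", "HC-like SMD"):
            if ref not in by_group:
                continue
            try:
                stats = oc.progression_stats(counts, "AD-like SMD", ref)
            except (KeyError, ZeroDivisionError):
                continue
            entry = {"contrast": f"AD-like SMD vs {ref}",
                     "proportions": stats}
            ea, eb = ev("AD-like SMD"), ev(ref)
            if any(f for _, f in ea + eb):
                lr = oc.logrank(ea, eb)
                entry["logrank"] = lr
                pvals.append(lr["p"])
                contrasts.append(entry["contrast"])
                try:
                    entry["incidence_rate_ratio"] = round(
                        oc.incidence_rate_ratio(ea, eb), 3)
                except ZeroDivisionError:
                    pass
            report.setdefault("contrasts", []).append(entry)
    if pvals:
        bh = oc.bh_correct(pvals, q=bh_q)
        report["bh"] = {"contrasts": contrasts,
                        "p_raw": pvals,
                        "p_adjusted": [float(x) for x in bh["adjusted"]],
                        "reject": [bool(x) for x in bh["reject"]],
                        "q": bh_q}
    curves = {}
    for g, os_ in by_group.items():
        events = oc.events_from_outcomes(os_)
        if events:
            c = oc.km_curve(events)
            curves[g] = {"times": c.times.tolist(),
                         "survival": c.survival.tolist(),
                         "at_risk": c.at_risk.tolist(),
                         "events": c.events.tolist()}
    report["km_curves"] = curves
    return report


def run_pipeline(config: RunConfig, schema: ROISchema | None = None) -> dict:
    """Execute every stage and write the artifact bundle to ``out_dir``.

    Returns the report dictionary (also written as ``report.json``).
    Identical config + seed gives byte-identical artifacts.
    """
    schema = schema or default_schema()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                    "settings": {
                        "disease": config.disease, "control": config.control,
                        "folds": config.folds, "cutoff": config.cutoff,
                        "icv_mode": config.icv_mode, "bh_q": config.bh_q,
                    }}

    # --- simulate / load ---------------------------------------------------
    try:
        if config.cohort_path is None:
            sim = dataclasses.replace(config.simulation,
                                      seed=_subseed(config.seed, "simulate"))
            cohort = generate_cohort(sim, schema)
            followup = generate_followup(cohort, sim)
            write_cohort_table(cohort, out / "cohort.csv")
            write_followup_table(followup, out / "followup.csv")
        else:
            cohort = read_cohort_table(config.cohort_path, schema)
            followup = None  # read lazily in the outcomes stage
    except StageError:
        raise
    except Exception as e:
        raise StageError("input", str(e)) from e

    # --- fit ----------------------------------------------------------------
    try:
        model, cv = fit_severity_model(
            cohort, schema, disease=config.disease, control=config.control,
            folds=config.folds, n_orth=config.n_orth, max_orth=config.max_orth,
            seed=_subseed(config.seed, "folds"), icv_mode=config.icv_mode)
        model.save(out / "model.json")
        feats = build_feature_matrix(cohort, schema,
                                     {config.disease, config.control})
        from .preprocess import preprocess_apply
        Z = preprocess_apply(feats, schema, model.scaling)
        top = variable_importance(model, Z.values, top_k=25)
        report["model"] = {
            "q2": round(cv.q2, 4), "sensitivity": round(cv.sensitivity, 4),
            "specificity": round(cv.specificity, 4), "n_orth": model.n_orth,
            "top_variables": [{"feature": f, "covariance": round(cv_, 4),
                               "correlation": round(cr, 4)}
                              for f, cv_, cr in top],
        }
    except Exception as e:
        raise StageError("fit", str(e)) from e

    # --- project + classify -------------------------------------------------
    try:
        results = compute_index(model, cohort, schema, config.target_group)
        results = classify(results, cutoff=config.cutoff)
        frame = results_to_frame(results)
        frame.to_csv(out / "index.csv", index=False,
                     float_format="%.6f")
        report["subtypes"] = subtype_counts(results)
        report["subtypes"]["cutoff"] = config.cutoff
    except Exception as e:
        raise StageError("project", str(e)) from e

    # --- validate -----------------------------------------------------------
    if followup is None and config.followup_path is None \
            and config.cohort_path is not None:
        report["validation"] = None
    else:
        try:
            if followup is None:
                followup = read_followup_table(config.followup_path)
            report["validation"] = validate_subtypes(
                followup, cohort, frame, bh_q=config.bh_q)
        except Exception as e:
            raise StageError("outcomes", str(e)) from e

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
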