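"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a memory-clinic style baseline cohort of four
groups — healthy controls (HC), subjective memory decline (SMD), mild
cognitive impairment (MCI) and Alzheimer's disease (AD) — with default
group sizes 69/86/45/38.  Disease-pattern carriers (all AD subjects,
MCI at half strength, and a planted AD-like subpopulation of the SMD
group, 11 of 86 by default) receive standardized mean shifts on a
configurable set of regions: reduced hippocampus, amygdala, entorhinal,
inferior-parietal and precuneus measures and enlarged inferior lateral
ventricles.  Volumes are multiplicatively coupled to a subject-level
total intracranial volume, and features share a single-parameter
exchangeable correlation within blocks (cortical thickness, cortical
volume, subcortical volume).

Follow-up outcomes, amyloid-PET SUVR values and MMSE/CDR-SOB
trajectories are sampled per (group x hidden-truth) stratum so that
downstream subtype-validation code is exercised end to end.  Hidden
truth labels are written to a ``truth_ad_like`` side-channel column
that never enters feature matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CohortTable, FOLLOWUP_COLUMNS
from .schema import ROISchema, default_schema

# --- default atrophy pattern -------------------------------------------------

#: Region keys of the default disease pattern.  Negative d = reduced in
#: AD-pattern carriers; ventricles enlarge.
DEFAULT_PATTERN_REGIONS = (
    "hippocampus",
    "entorhinal",
    "inferiorparietal",
    "amygdala",
    "precuneus",
)
DEFAULT_VENTRICLE_REGIONS = ("Inf-Lat-Vent",)


def default_effect_map(d: float = 2.5, ventricle_d: float = 2.0) -> dict[str, float]:
    """Named-region effect map for the default AD atrophy pattern."""
    m = {r: -abs(d) for r in DEFAULT_PATTERN_REGIONS}
    m.update({r: abs(ventricle_d) for r in DEFAULT_VENTRICLE_REGIONS})
    return m


def make_atrophy_pattern(schema: ROISchema, effect_map: dict[str, float],
                         default_d: float | None = None) -> np.ndarray:
    """Expand a named-region effect map into a per-feature effect vector.

    Keys may be exact feature names or region stems (expanded to every
    matching measure: both hemispheres, thickness and volume).  Entries
    mapped to ``None`` take ``default_d``.  Features outside the map
    stay at zero.  Unknown keys raise ``KeyError``.
    """
    d = np.zeros(len(schema))
    for key, val in effect_map.items():
        if val is None:
            if default_d is None:
                raise ValueError(f"effect for {key!r} is None and no default_d given")
            val = default_d
        for name in schema.match(key):
            d[schema.index_of(name)] = float(val)
    return d


# --- configuration -----------------------------------------------------------

OUTCOMES = ("HC", "SMD", "MCI", "AD", "PD", "died")

#: Default follow-up outcome probabilities per (group, truth) stratum.
#: Probabilities may sum to less than 1; the remainder is the chance of
#: missing follow-up (no visits past baseline).
DEFAULT_OUTCOME_PROBS: dict[str, dict[str, float]] = {
    "HC": {"HC": 35 / 69, "SMD": 25 / 69, "MCI": 7 / 69, "died": 1 / 69},
    "SMD_HC_like": {"HC": 11 / 75, "SMD": 50 / 75, "MCI": 9 / 75,
                    "AD": 1 / 75, "died": 3 / 75},
    "SMD_AD_like": {"SMD": 3 / 11, "AD": 6 / 11, "died": 2 / 11},
    "MCI": {"HC": 1 / 45, "SMD": 2 / 45, "MCI": 14 / 45, "AD": 17 / 45,
            "PD": 1 / 45, "died": 8 / 45},
    "AD": {"AD": 19 / 38, "died": 9 / 38},
}

DEFAULT_SUVR_PARAMS: dict[str, tuple[float, float]] = {
    "HC": (1.20, 0.20),
    "SMD_HC_like": (1.22, 0.22),
    "SMD_AD_like": (1.80, 0.30),
    "MCI": (1.60, 0.35),
    "AD": (2.10, 0.35),
}

#: MMSE: (baseline mean, slope per month); CDR-SOB likewise.
DEFAULT_MMSE_PARAMS: dict[str, tuple[float, float]] = {
    "HC": (29.0, -0.004),
    "SMD_HC_like": (29.0, -0.002),
    "SMD_AD_like": (28.5, -0.030),
    "MCI": (27.0, -0.050),
    "AD": (23.0, -0.150),
}
DEFAULT_CDR_PARAMS: dict[str, tuple[float, float]] = {
    "HC": (0.0, 0.001),
    "SMD_HC_like": (0.1, 0.001),
    "SMD_AD_like": (0.5, 0.015),
    "MCI": (1.5, 0.030),
    "AD": (4.5, 0.080),
}


@dataclass
class SimulationConfig:
    """Everything that determines one synthetic cohort draw."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 69, "SMD": 86, "MCI": 45, "AD": 38})
    n_ad_like_smd: int = 11
    effect_map: dict[str, float] = field(default_factory=default_effect_map)
    mci_effect_fraction: float = 0.5
    feature_correlation: float = 0.3
    thickness_base: float = 2.5        # [mm]
    thickness_sd: float = 0.15         # [mm]
    volume_cv: float = 0.12            # fractional sd of volumes
    icv_mean: float = 1.5e6            # [mm^3]
    icv_sd: float = 1.5e5              # [mm^3]
    icv_volume_coupling: float = 1.0   # power-law exponent
    suvr_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUVR_PARAMS))
    followup_visit_months: tuple[int, ...] = (0, 18, 36, 54, 72, 90)
    outcome_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OUTCOME_PROBS.items()})
    mmse_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MMSE_PARAMS))
    cdr_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CDR_PARAMS))
    subject_prefix: str = "S"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.feature_correlation < 1:
            raise ValueError("feature_correlation must lie in [0, 1)")
        if self.n_ad_like_smd > self.group_sizes.get("SMD", 0):
            raise ValueError("n_ad_like_smd exceeds the SMD group size")
        months = self.followup_visit_months
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("followup_visit_months must be strictly increasing")
        for stratum, probs in self.outcome_probs.items():
            unknown = set(probs) - set(OUTCOMES)
            if unknown:
                raise ValueError(f"unknown outcomes {unknown} in stratum {stratum!r}")
            total = sum(probs.values())
            if total > 1 + 1e-9 or any(p < 0 for p in probs.values()):
                raise ValueError(
                    f"outcome probabilities for {stratum!r} malformed (sum {total:.3f})")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _blocks(schema: ROISchema) -> np.ndarray:
    """Correlation-block id per feature: 0 cortical thickness, 1 cortical
    volume, 2 subcortical volume."""
    out = np.empty(len(schema), int)
    for j, e in enumerate(schema):
        if e.kind == "thickness":
            out[j] = 0
        elif e.name.startswith(("lh_", "rh_")):
            out[j] = 1
        else:
            out[j] = 2
    return out


def _volume_bases(schema: ROISchema) -> np.ndarray:
    """Plausible baseline volumes [mm^3] per feature (thickness entries unused).

    Known structures get anatomically sensible magnitudes; remaining
    volumes get a fixed mid-range default.  Bases are deterministic
    (they depend only on the schema), keeping the closed-form group
    means of the generator easy to state.
    """
    known = {
        "hippocampus": 4000.0, "amygdala": 1700.0, "thalamus": 7500.0,
        "caudate": 3600.0, "putamen": 5000.0, "pallidum": 1700.0,
        "accumbens": 600.0, "inflatvent": 500.0, "lateralventricle": 9000.0,
    }
    base = np.full(len(schema), 4000.0)
    from .schema import _stem  # shared region-stem normalisation
    for j, e in enumerate(schema):
        if e.kind != "volume":
            continue
        stem = _stem(e.name)
        for key, v in known.items():
            if key in stem:
                base[j] = v
                break
    return base


def generate_cohort(config: SimulationConfig,
                    schema: ROISchema | None = None) -> CohortTable:
    """Draw one baseline cohort; identical (config, seed) gives identical output.

    Features for each subject are ``base + scale * z`` (thickness) or
    ``base * (icv/icv_mean)^coupling * (1 + cv * z)`` (volume), where z
    is standard normal with block-exchangeable correlation and a mean
    shift of d (the configured effect, in within-group standard
    deviations of z) for disease-pattern carriers.
    """
    schema = schema or default_schema()
    rng = np.random.default_rng(config.seed)
    d_vec = make_atrophy_pattern(schema, config.effect_map)
    blocks = _blocks(schema)
    vol_base = _volume_bases(schema)
    vol_mask = np.array(schema.volume_mask())
    rho = config.feature_correlation

    rows = []
    sid = 0
    for group in ("HC", "SMD", "MCI", "AD"):
        n = config.group_sizes.get(group, 0)
        # hidden truth: which subjects carry the disease pattern
        if group == "SMD":
            carrier = np.zeros(n, bool)
            carrier[rng.choice(n, size=config.n_ad_like_smd, replace=False)] = True
            frac = np.where(carrier, 1.0, 0.0)
        elif group == "AD":
            carrier = np.ones(n, bool)
            frac = np.ones(n)
        elif group == "MCI":
            carrier = np.ones(n, bool)
            frac = np.full(n, config.mci_effect_fraction)
        else:
            carrier = np.zeros(n, bool)
            frac = np.zeros(n)

        for i in range(n):
            shared = rng.standard_normal(3)          # one factor per block
            eps = rng.standard_normal(len(schema))
            z = np.sqrt(rho) * shared[blocks] + np.sqrt(1 - rho) * eps
            z += frac[i] * d_vec
            icv = rng.normal(config.icv_mean, config.icv_sd)
            icv = max(icv, 0.5 * config.icv_mean)    # guard against absurd draws
            feats = np.where(
                vol_mask,
                vol_base * (icv / config.icv_mean) ** config.icv_volume_coupling
                * (1 + config.volume_cv * z),
                config.thickness_base + config.thickness_sd * z,
            )
            stratum = _stratum(group, bool(carrier[i]))
            mu_s, sd_s = config.suvr_params[stratum]
            suvr = max(0.5, rng.normal(mu_s, sd_s))
            rows.append({
                "subject_id": f"{config.subject_prefix}{sid:04d}",
                "group": group,
                "age": round(float(np.clip(rng.normal(73, 7), 55, 95)), 1),
                "sex": "F" if rng.random() < 0.55 else "M",
                "education": int(rng.integers(0, 5)),
                "icv": round(float(icv), 1),
                "suvr": round(float(suvr), 3),
                "apoe_e4_count": int(rng.choice(
                    [0, 1, 2], p=[0.6, 0.33, 0.07] if not carrier[i]
                    else [0.3, 0.5, 0.2])),
                # hidden truth: the planted AD-like subpopulation of SMD
                "truth_ad_like": int(carrier[i] and group == "SMD"),
                **{name: float(v) for name, v in zip(schema.names, feats)},
            })
            sid += 1
    df = pd.DataFrame(rows)
    return CohortTable(df, schema)


def _stratum(group: str, ad_like: bool) -> str:
    if group == "SMD":
        return "SMD_AD_like" if ad_like else "SMD_HC_like"
    return group


_BASELINE_DIAGNOSIS = {"HC": "HC", "SMD": "SMD", "MCI": "MCI", "AD": "AD"}


def generate_followup(cohort: CohortTable, config: SimulationConfig) -> pd.DataFrame:
    """Sample follow-up visit records for every cohort subject.

    Each subject draws a final outcome from its (group x truth) stratum
    distribution; progressors and deaths get an event visit uniform on
    the post-baseline grid, subjects with missing follow-up keep only
    the baseline row, and everyone else attends the full grid.  MMSE
    and CDR-SOB follow linear group trajectories with noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
    months = list(config.followup_visit_months)
    post = months[1:]
    recs = []
    for _, row in cohort.data.iterrows():
        group = row["group"]
        ad_like = bool(row.get("truth_ad_like", 0))
        stratum = _stratum(group, ad_like)
        probs = config.outcome_probs.get(stratum, config.outcome_probs.get(group, {}))
        labels = list(probs.keys()) + ["__missing__"]
        pvec = list(probs.values())
        pvec.append(max(0.0, 1.0 - sum(pvec)))
        outcome = str(rng.choice(labels, p=np.asarray(pvec) / sum(pvec)))

        base_dx = _BASELINE_DIAGNOSIS[group]
        mmse0, mmse_slope = config.mmse_params[stratum]
        cdr0, cdr_slope = config.cdr_params[stratum]

        def visit(month: int, dx: str, vital: str) -> dict:
            mmse = int(np.clip(round(mmse0 + mmse_slope * month
                                     + rng.normal(0, 1.0)), 0, 30))
            cdr = float(np.clip(round((cdr0 + cdr_slope * month
                                       + rng.normal(0, 0.3)) * 2) / 2, 0, 18))
            return {"subject_id": row["subject_id"], "month": month,
                    "diagnosis": dx, "mmse": mmse, "cdr_sob": cdr,
                    "vital_status": vital}

        recs.append(visit(0, base_dx, "alive"))
        if outcome == "__missing__":
            continue
        event_month = int(rng.choice(post))
        if outcome == "died":
            for m in post:
                if m < event_month:
                    recs.append(visit(m, base_dx, "alive"))
                elif m == event_month:
                    recs.append(visit(m, base_dx, "died"))
            continue
        is_change = outcome != base_dx
        for m in post:
            if is_change and m >= event_month:
                recs.append(visit(m, outcome, "alive"))
            else:
                recs.append(visit(m, base_dx, "alive"))
    return pd.DataFrame(recs, columns=FOLLOWUP_COLUMNS)
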