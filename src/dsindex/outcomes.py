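"""Follow-up validation: outcome tables, progression statistics, survival.

Subjects are categorized *stable* if they stay in their baseline
diagnostic category (moves between the cognitively-normal labels HC and
SMD do not count) and *progressive* if they move to a worse category —
MCI, any dementia — or die.  Severity ordering: HC = SMD < MCI <
dementia (AD or other).  Event time is the month of the first visit at
which the worsening or death is recorded; stable subjects are censored
at their last attended visit.

Kaplan-Meier curves and the log-rank test are delegated to lifelines,
and Benjamini-Hochberg correction to statsmodels, behind this module's
interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

#: diagnosis → severity category (HC and SMD are both cognitively normal)
_SEVERITY = {"HC": 0, "SMD": 0, "MCI": 1, "AD": 2, "PD": 2}

OUTCOME_LABELS = ("HC", "SMD", "MCI", "AD", "PD", "died", "missing")

#: outcomes counted as progression for baseline cognitively-normal groups
PROGRESSION_LABELS = ("MCI", "AD", "PD", "died")


def _round1(x: float) -> float:
    """Round to 1 decimal, half away from zero (printed-table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SubjectOutcome:
    subject_id: str
    outcome: str          # one of OUTCOME_LABELS
    month: float          # event month, or censor month for stable subjects
    is_event: bool


@dataclass
class SurvivalCurve:
    """Product-limit estimate over the observed event times."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
        return s


def final_outcome(visits: pd.DataFrame) -> SubjectOutcome:
    """Resolve one subject's follow-up record to a final outcome.

    ``visits`` holds that subject's rows of a follow-up table, ordered
    by month with the baseline visit first.  The outcome is the first
    visit whose diagnosis is in a worse severity category than baseline,
    or death, whichever comes first; otherwise the subject is stable
    and carries the diagnosis of the last attended visit, censored
    there.  A record with no post-baseline visits is a missing outcome.
    """
    if visits.empty:
        raise ValueError("subject has no visits")
    visits = visits.sort_values("month")
    sid = str(visits["subject_id"].iloc[0])
    months = visits["month"].to_numpy(float)
    if months[0] != 0:
        raise ValueError(f"baseline visit absent for subject {sid!r}")
    if len(visits) == 1:
        return SubjectOutcome(sid, "missing", 0.0, False)
    base_sev = _severity(visits["diagnosis"].iloc[0], sid)
    for _, v in visits.iloc[1:].iterrows():
        if str(v["vital_status"]).lower() in ("died", "dead", "deceased"):
            return SubjectOutcome(sid, "died", float(v["month"]), True)
        dx = str(v["diagnosis"])
        if _severity(dx, sid) > base_sev:
            return SubjectOutcome(sid, dx, float(v["month"]), True)
    last = visits.iloc[-1]
    return SubjectOutcome(sid, str(last["diagnosis"]), float(last["month"]), False)


def _severity(dx: str, sid: str) -> int:
    try:
        return _SEVERITY[str(dx)]
    except KeyError:
        raise ValueError(f"unknown diagnosis {dx!r} for subject {sid!r}") from None


def subject_outcomes(followup: pd.DataFrame) -> list[SubjectOutcome]:
    """Per-subject outcomes for a long-format follow-up table, input order."""
    order = followup["subject_id"].astype(str).drop_duplicates().tolist()
    by_id = dict(tuple(followup.groupby("subject_id", sort=False)))
    return [final_outcome(by_id[sid]) for sid in order]


def outcome_table(followup: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Tabulate final outcomes per analysis group (Table-of-counts form).

    ``groups`` maps every subject id to its analysis group (for example
    "HC", "HC-like SMD", "AD-like SMD", "MCI", "AD").  Returns a
    groups x OUTCOME_LABELS count table; missing follow-up is its own
    column so each row sums to the group size.
    """
    outs = subject_outcomes(followup)
    unmapped = [o.subject_id for o in outs if o.subject_id not in groups]
    if unmapped:
        raise KeyError(f"subjects not mapped to an analysis group: {unmapped[:5]}")
    group_names = list(dict.fromkeys(groups.values()))
    table = pd.DataFrame(0, index=group_names, columns=list(OUTCOME_LABELS))
    for o in outs:
        table.loc[groups[o.subject_id], o.outcome] += 1
    return table


def progression_stats(counts: pd.DataFrame, group_a: str, group_b: str) -> dict:
    """Progression proportions and their ratio for two analysis groups.

    The progressed count is MCI + any dementia + died; the denominator
    is the group's subjects with a recorded outcome (missing excluded).
    Percentages and the ratio are reported to 1 decimal, half away from
    zero; unrounded values are carried alongside.  Intended for groups
    whose baseline category is cognitively normal.
    """
    out = {}
    props = {}
    for g in (group_a, group_b):
        if g not in counts.index:
            raise KeyError(f"group {g!r} absent from outcome table")
        row = counts.loc[g]
        denom = int(row.drop("missing").sum())
        if denom == 0:
            raise ZeroDivisionError(f"group {g!r} has no recorded outcomes")
        prog = int(row[list(PROGRESSION_LABELS)].sum())
        props[g] = prog / denom
        out[g] = {"progressed": prog, "n": denom,
                  "percent": _round1(100 * prog / denom)}
    if props[group_b] == 0:
        raise ZeroDivisionError(f"zero progression proportion in {group_b!r}")
    out["ratio"] = _round1(props[group_a] / props[group_b])
    return out


def incidence_rate_ratio(events_a, events_b) -> float:
    """Time-aware ratio of progression rates: events per person-month.

    Complements the plain proportion ratio when follow-up lengths
    differ between groups.
    """
    def rate(events):
        t = sum(e[0] for e in events)
        d = sum(1 for e in events if e[1])
        if t <= 0:
            raise ZeroDivisionError("no person-time accrued")
        return d / t
    rb = rate(events_b)
    if rb == 0:
        raise ZeroDivisionError("no events in reference group")
    return rate(events_a) / rb


def events_from_outcomes(outcomes: list[SubjectOutcome],
                         include_missing: bool = False) -> list[tuple[float, bool]]:
    """(time, is_event) pairs for survival analysis."""
    return [(o.month, o.is_event) for o in outcomes
            if include_missing or o.outcome != "missing"]


def km_curve(events: list[tuple[float, bool]]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate from (time, is_event) pairs."""
    if not events:
        raise ValueError("no subjects supplied")
    times = np.asarray([e[0] for e in events], float)
    flags = np.asarray([bool(e[1]) for e in events])
    if np.any(times < 0):
        raise ValueError("negative event time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=flags)
    ev = kmf.event_table
    grid = ev.index.to_numpy(float)
    return SurvivalCurve(
        times=grid,
        at_risk=ev["at_risk"].to_numpy(float),
        events=ev["observed"].to_numpy(float),
        survival=kmf.survival_function_["KM_estimate"].to_numpy(float),
    )


def logrank(events_a: list[tuple[float, bool]],
            events_b: list[tuple[float, bool]]) -> dict:
    """Two-group log-rank test; chi-square statistic with 1 df."""
    if not any(e[1] for e in events_a + events_b):
        raise ValueError("log-rank undefined with no events")
    ta = np.asarray([e[0] for e in events_a], float)
    tb = np.asarray([e[0] for e in events_b], float)
    if np.any(ta < 0) or np.any(tb < 0):
        raise ValueError("negative event time")
    res = logrank_test(ta, tb,
                       event_observed_A=[bool(e[1]) for e in events_a],
                       event_observed_B=[bool(e[1]) for e in events_b])
    return {"chi2": float(res.test_statistic), "df": 1, "p": float(res.p_value)}


def dichotomize_mmse(scores) -> list[str]:
    """MMSE >= 24 is normal global cognition; below 24 abnormal."""
    out = []
    for s in np.asarray(scores).ravel():
        if not float(s).is_integer() or not 0 <= s <= 30:
            raise ValueError(f"MMSE score {s!r} outside 0-30")
        out.append("normal" if s >= 24 else "abnormal")
    return out


def classify_pib(suvr: float) -> str:
    """Amyloid-PET positivity: SUVR >= 1.5 is positive."""
    if not np.isfinite(suvr) or suvr <= 0:
        raise ValueError(f"SUVR must be positive, got {suvr!r}")
    return "positive" if suvr >= 1.5 else "negative"


def bh_correct(pvalues, q: float = 0.05) -> dict:
    """Benjamini-Hochberg step-up FDR correction at level q.

    Returns adjusted p-values (original order) and rejection flags.
    """
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        return {"adjusted": np.array([]), "reject": np.array([], bool)}
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return {"adjusted": adjusted, "reject": reject}


# ---------------------------------------------------------------------------
# Worked example: published follow-up outcome frequencies for a
# preclinical-dementia cohort (counts per analysis group), used to
# check the tabulation and progression arithmetic end to end.
# ---------------------------------------------------------------------------

REFERENCE_OUTCOME_COUNTS: dict[str, dict[str, int]] = {
    "HC":          {"HC": 35, "SMD": 25, "MCI": 7, "AD": 0, "PD": 0,
                    "died": 1, "missing": 1},
    "HC-like SMD": {"HC": 11, "SMD": 50, "MCI": 9, "AD": 1, "PD": 0,
                    "died": 3, "missing": 1},
    "AD-like SMD": {"HC": 0, "SMD": 3, "MCI": 0, "AD": 6, "PD": 0,
                    "died": 2, "missing": 0},
    "MCI":         {"HC": 1, "SMD": 2, "MCI": 14, "AD": 17, "PD": 1,
                    "died": 8, "missing": 2},
    "AD":          {"HC": 0, "SMD": 0, "MCI": 0, "AD": 19, "PD": 0,
                    "died": 9, "missing": 10},
}

_BASELINE_DX = {"HC": "HC", "HC-like SMD": "SMD", "AD-like SMD": "SMD",
                "MCI": "MCI", "AD": "AD"}


def followup_from_counts(counts: dict[str, dict[str, int]],
                         event_month: int = 36, censor_month: int = 90,
                         ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Construct subject-level visit records realizing an outcome-count table.

    Deterministic scaffold for worked examples: every progression or
    death is recorded at ``event_month``; stable subjects attend through
    ``censor_month`` (label switches within the cognitively-normal
    categories happen at the first follow-up visit).  Returns the
    long-format table plus the subject → analysis-group map.
    """
    recs, groups = [], {}
    sid = 0
    for group, row in counts.items():
        base = _BASELINE_DX[group]
        for outcome, n in row.items():
            for _ in range(int(n)):
                subject = f"T{sid:04d}"
                sid += 1
                groups[subject] = group

                def visit(month, dx, vital="alive"):
                    recs.append({"subject_id": subject, "month": month,
                                 "diagnosis": dx, "mmse": 28, "cdr_sob": 0.0,
                                 "vital_status": vital})

                visit(0, base)
                if outcome == "missing":
                    continue
                if outcome == "died":
                    visit(event_month, base, vital="died")
                elif _SEVERITY[outcome] > _SEVERITY[base]:
                    visit(event_month, outcome)
                    visit(censor_month, outcome)
                else:
                    visit(18, outcome)
                    visit(censor_month, outcome)
    return pd.DataFrame(recs), groups
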