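"""Milestone acquisition curves, score summaries and onset-outcome tests.

Milestone quantiles default to the achievers-only convention (empirical
quantiles of age-at-acquisition among patients who achieved the milestone);
a Kaplan-Meier mode over all assessed patients, censoring non-achievers at
their last assessment, is available because achievers-only conditioning is
optimistic whenever follow-up is short. Standardized assessment scores
(GMFM-66-IS 0-100, PDMS-2 raw 0-100) are summarized per age bin; five-level
classification scales (GMFCS-ER, MACS, CFCS; Level I best) are tallied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .asm_effectiveness import EffectEstimate, fisher_or
from .cohort_model import AssessmentRecord, Cohort, MilestoneRecord
from .seizure_course import detect_onset, km_fit, km_quantiles

# record types re-exported from the core model
__all__ = [
    "MilestoneRecord",
    "AssessmentRecord",
    "CDC_REFERENCE_AGES_MONTHS",
    "SCORE_SCALES",
    "LEVEL_SCALES",
    "achieved_fraction",
    "milestone_quantiles",
    "onset_outcome_association",
    "score_summary",
    "format_age",
]

#: Static reference annotation: ages (months) by which 75% of typically
#: developing children achieve each milestone (public CDC developmental
#: milestone checklists). Annotation only — never computed from cohort data.
CDC_REFERENCE_AGES_MONTHS: dict[str, float] = {
    "head_control": 4.0,
    "roll_over": 6.0,
    "sit_unassisted": 9.0,
    "grasp": 6.0,
    "walk": 15.0,
    "walk_unassisted": 18.0,
    "first_words": 15.0,
}

SCORE_SCALES = frozenset({"gmfm66is", "pdms2_grasping", "pdms2_vmi"})
LEVEL_SCALES = frozenset({"gmfcs_er", "macs", "cfcs"})
_LEVELS = ["I", "II", "III", "IV", "V"]


def achieved_fraction(cohort: Cohort, milestone: str) -> tuple[int, int, float]:
    """(n_achieved, n_assessed, fraction) for one milestone.

    The fraction is rounded to 2 decimals for reporting; the raw counts are
    always carried alongside.
    """
    records = [m for m in cohort.milestones if m.milestone == milestone]
    if not records:
        raise ValueError(f"milestone never assessed in this cohort: {milestone!r}")
    n_assessed = len(records)
    n_achieved = sum(m.achieved for m in records)
    return n_achieved, n_assessed, round(n_achieved / n_assessed, 2)


def milestone_quantiles(cohort: Cohort, milestone: str,
                        q: tuple[float, ...] = (0.25, 0.5, 0.75, 0.9), *,
                        mode: str = "achievers", min_achievers: int = 5
                        ) -> dict[float, float | None] | None:
    """Age-at-acquisition quantiles (months) for one milestone.

    ``mode="achievers"`` (default) takes empirical quantiles among patients
    who achieved the milestone; ``mode="km"`` estimates Kaplan-Meier
    quantiles over all assessed patients, censoring non-achievers at their
    last assessment. Returns None (not computed) with fewer than
    ``min_achievers`` achievers.
    """
    records = [m for m in cohort.milestones if m.milestone == milestone]
    if not records:
        raise ValueError(f"milestone never assessed in this cohort: {milestone!r}")
    ages = [m.age_achieved_months for m in records if m.achieved]
    if len(ages) < min_achievers:
        return None
    if mode == "achievers":
        arr = np.asarray(ages, dtype=float)
        return {qi: float(np.quantile(arr, qi, method="inverted_cdf")) for qi in q}
    if mode == "km":
        censored = [m.age_last_assessed_months for m in records if not m.achieved]
        curve = km_fit(ages, censored)
        return km_quantiles(curve, q)
    raise ValueError(f"unknown mode {mode!r}")


def _onset_strata(cohort: Cohort) -> dict[str, str]:
    """patient_id -> 'neonatal' | 'later' (epileptic patients only)."""
    strata = {}
    for pid in cohort.patients:
        hist = cohort.histories.get(pid)
        if hist is None:
            continue
        onset = detect_onset(hist)
        if onset is None:
            continue
        strata[pid] = "neonatal" if onset == 1 else "later"
    return strata


def onset_outcome_association(cohort: Cohort, outcome: str
                              ) -> EffectEstimate | dict:
    """Association between onset timing (neonatal vs later) and an outcome.

    Binary milestones -> Fisher OR of achievement for later vs neonatal
    onset; level scales (GMFCS-ER/MACS/CFCS) -> Wilcoxon rank-sum on levels;
    score scales -> Spearman correlation of score with onset month (ordinal
    robustness). Raises on empty strata; a constant outcome is reported with
    a note instead of a statistic.
    """
    strata = _onset_strata(cohort)
    milestone_names = {m.milestone for m in cohort.milestones}
    if outcome in milestone_names:
        table = np.zeros((2, 2), dtype=int)   # later/neonatal x achieved/not
        for m in cohort.milestones:
            if m.milestone != outcome or m.patient_id not in strata:
                continue
            i = 0 if strata[m.patient_id] == "later" else 1
            table[i, 0 if m.achieved else 1] += 1
        if table[0].sum() == 0 or table[1].sum() == 0:
            raise ValueError("both onset strata must be nonempty")
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            return {"outcome": outcome, "note": "constant outcome; OR undefined"}
        est = fisher_or(table)
        return EffectEstimate(drug="", outcome=outcome, table=est.table,
                              or_point=est.or_point, ci_low=est.ci_low,
                              ci_high=est.ci_high, p_value=est.p_value,
                              n_patients=int(table.sum()))
    if outcome in LEVEL_SCALES:
        groups: dict[str, list[int]] = {"neonatal": [], "later": []}
        for a in cohort.assessments:
            if a.scale == outcome and a.patient_id in strata:
                groups[strata[a.patient_id]].append(_LEVELS.index(str(a.value)) + 1)
        if not groups["neonatal"] or not groups["later"]:
            raise ValueError("both onset strata must be nonempty")
        if len(set(groups["neonatal"] + groups["later"])) == 1:
            return {"outcome": outcome, "note": "constant outcome"}
        res = stats.mannwhitneyu(groups["neonatal"], groups["later"],
                                 alternative="two-sided")
        return {"outcome": outcome, "test": "rank_sum",
                "statistic": float(res.statistic), "p": float(res.pvalue),
                "n": len(groups["neonatal"]) + len(groups["later"])}
    if outcome in SCORE_SCALES:
        onset_ages, scores = [], []
        onsets = {pid: detect_onset(cohort.histories[pid])
                  for pid in cohort.patients if pid in strata}
        for a in cohort.assessments:
            if a.scale == outcome and a.patient_id in onsets:
                onset_ages.append(onsets[a.patient_id])
                scores.append(float(a.value))
        if len(scores) < 3:
            raise ValueError("need >= 3 paired observations")
        if len(set(scores)) == 1 or len(set(onset_ages)) == 1:
            return {"outcome": outcome, "note": "constant outcome"}
        rho, p = stats.spearmanr(onset_ages, scores)
        return {"outcome": outcome, "test": "spearman", "rho": float(rho),
                "p": float(p), "n": len(scores)}
    raise ValueError(f"unknown outcome {outcome!r}")


def score_summary(cohort: Cohort, scale: str,
                  age_bins: list[tuple[float, float]] = (
                      (0, 12), (12, 24), (24, 60), (60, float("inf"))), *,
                  q: tuple[float, ...] = (0.25, 0.5, 0.75, 0.9),
                  min_count: int = 1) -> pd.DataFrame:
    """Per-age-bin quantiles (score scales) or level tallies (level scales).

    Bins are half-open [lo, hi) in months; bins with fewer than
    ``min_count`` records are suppressed with a note column.
    """
    if scale in SCORE_SCALES:
        rows = []
        for lo, hi in age_bins:
            vals = [float(a.value) for a in cohort.assessments
                    if a.scale == scale and lo <= a.age_months < hi]
            row = {"bin_lo_months": lo, "bin_hi_months": hi, "n": len(vals)}
            if len(vals) >= min_count:
                for qi in q:
                    row[f"q{int(qi * 100)}"] = float(np.quantile(vals, qi))
                row["note"] = ""
            else:
                row["note"] = "suppressed: too few exams"
            rows.append(row)
        return pd.DataFrame(rows)
    if scale in LEVEL_SCALES:
        rows = []
        for lo, hi in age_bins:
            vals = [str(a.value) for a in cohort.assessments
                    if a.scale == scale and lo <= a.age_months < hi]
            row = {"bin_lo_months": lo, "bin_hi_months": hi, "n": len(vals)}
            for lvl in _LEVELS:
                row[f"level_{lvl}"] = vals.count(lvl)
            row["note"] = "" if len(vals) >= min_count else "suppressed: too few exams"
            rows.append(row)
        return pd.DataFrame(rows)
    raise ValueError(f"unknown scale {scale!r}")


def format_age(months: float | None) -> str:
    """Mixed months/years age formatting for reports (<24 mo in months)."""
    if months is None or (isinstance(months, float) and np.isnan(months)):
        return "not reached"
    if months < 24:
        return f"{months:g} months"
    return f"{months / 12:.1f} years"
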