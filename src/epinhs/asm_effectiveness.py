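"""Patient-month treatment-response classification and comparative
effectiveness of anti-seizure medications (ASMs).

The unit of analysis is the patient-month: each evaluable month of
follow-up is classified by comparing its SF score to the previous month
(reduced / unchanged-or-worse / freedom-maintained), tagged with the set of
drugs active that month, and aggregated into 2x2 exposed-vs-unexposed x
favorable-vs-unfavorable tables per drug. Odds ratios use the
cross-product with a Haldane-Anscombe 0.5 correction on zero cells, Woolf
(log-normal) 95% confidence intervals, and a two-sided Fisher's exact
p-value. A month under multiple drugs counts as exposed for each of them
(sole-exposure sensitivity mode available).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import OVERALL, AsmExposure, Cohort, SeizureHistory

# re-exported record type (defined with the core model to avoid import cycles)
__all__ = [
    "AsmExposure",
    "MonthResponse",
    "EffectEstimate",
    "classify_month",
    "month_response_table",
    "fisher_or",
    "comparative_effectiveness",
    "time_locked_response",
]

logger = logging.getLogger(__name__)

RESPONSE_CLASSES = ("reduced", "unchanged_or_worse", "freedom_maintained",
                    "not_evaluable")

FAVORABLE = {
    "short_term": {"reduced"},
    "long_term": {"reduced", "freedom_maintained"},
    "freedom_only": {"freedom_maintained"},
}


@dataclass(frozen=True)
class MonthResponse:
    patient_id: str
    month: int
    exposed_drugs: frozenset[str]
    response_class: str


@dataclass(frozen=True)
class EffectEstimate:
    drug: str
    outcome: str
    table: tuple[tuple[int, int], tuple[int, int]]  # exposed/unexposed x fav/unfav
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    n_patients: int


def classify_month(history: SeizureHistory, month: int, *,
                   seizure_type: str = OVERALL) -> str:
    """Classify one patient-month against the previous month.

    reduced: SF fell from a nonzero level; freedom_maintained: two
    consecutive seizure-free months after prior seizures; unchanged_or_worse:
    stayed at or above a nonzero level, or seizures (re)appeared;
    not_evaluable: months at or before onset of any seizure history.
    """
    series = history.series.get(seizure_type, {})
    cur = series.get(month, 0)
    prev = series.get(month - 1, 0)
    had_prior = any(series.get(m, 0) > 0 for m in series if m < month)
    if not had_prior:
        return "not_evaluable"
    if prev > 0 and cur < prev:
        return "reduced"
    if prev == 0 and cur == 0:
        return "freedom_maintained"
    return "unchanged_or_worse"


def month_response_table(cohort: Cohort, *, seizure_type: str = OVERALL,
                         sole_exposure: bool = False,
                         exclude_imputed: bool = False) -> pd.DataFrame:
    """All evaluable patient-months with exposure sets and response classes."""
    rows = []
    for pid, pat in cohort.patients.items():
        hist = cohort.histories.get(pid)
        if hist is None:
            continue
        for month in range(pat.observation_start_month + 1,
                           pat.observation_end_month + 1):
            if exclude_imputed and (
                    (pid, seizure_type, month) in cohort.imputed
                    or (pid, seizure_type, month - 1) in cohort.imputed):
                continue
            cls = classify_month(hist, month, seizure_type=seizure_type)
            if cls == "not_evaluable":
                continue
            drugs = cohort.drugs_active(pid, month)
            if sole_exposure and len(drugs) > 1:
                continue
            rows.append({"patient_id": pid, "month": month,
                         "exposed_drugs": frozenset(drugs),
                         "response_class": cls})
    return pd.DataFrame(rows, columns=["patient_id", "month", "exposed_drugs",
                                       "response_class"])


def fisher_or(table) -> EffectEstimate:
    """Fisher's exact p with Haldane-Anscombe-corrected OR and Woolf 95% CI.

    ``table`` is [[a, b], [c, d]] = exposed/unexposed x favorable/unfavorable
    counts. The p-value is the two-sided exact hypergeometric probability on
    the raw counts; the OR and CI use counts with 0.5 added to every cell
    whenever any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 nonnegative integer counts")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    c = t + 0.5 if (t == 0).any() else t
    or_point = (c[0, 0] * c[1, 1]) / (c[0, 1] * c[1, 0])
    se = math.sqrt((1 / c).sum())
    ci_low = math.exp(math.log(or_point) - 1.96 * se)
    ci_high = math.exp(math.log(or_point) + 1.96 * se)
    ti = t.astype(int)
    return EffectEstimate(
        drug="", outcome="",
        table=((ti[0, 0], ti[0, 1]), (ti[1, 0], ti[1, 1])),
        or_point=float(or_point), ci_low=float(ci_low), ci_high=float(ci_high),
        p_value=float(p), n_patients=0)


def _bootstrap_ci(months: pd.DataFrame, drug: str, favorable: set[str],
                  n_boot: int, seed: int) -> tuple[float, float]:
    """Patient-level bootstrap of the (corrected) OR."""
    rng = np.random.default_rng(seed)
    pids = months["patient_id"].unique()
    by_pid = {pid: g for pid, g in months.groupby("patient_id")}
    ors = []
    for _ in range(n_boot):
        sample = rng.choice(pids, size=len(pids), replace=True)
        tab = np.zeros((2, 2))
        for pid in sample:
            g = by_pid[pid]
            exp = g["exposed_drugs"].apply(lambda s: drug in s)
            fav = g["response_class"].isin(favorable)
            tab[0, 0] += (exp & fav).sum()
            tab[0, 1] += (exp & ~fav).sum()
            tab[1, 0] += (~exp & fav).sum()
            tab[1, 1] += (~exp & ~fav).sum()
        c = tab + 0.5 if (tab == 0).any() else tab
        ors.append((c[0, 0] * c[1, 1]) / (c[0, 1] * c[1, 0]))
    return tuple(np.quantile(ors, [0.025, 0.975]))


def comparative_effectiveness(cohort: Cohort, drug: str,
                              outcome: str = "short_term", *,
                              min_patients: int = 10,
                              sole_exposure: bool = False,
                              seizure_type: str = OVERALL,
                              ci: str = "woolf",
                              n_boot: int = 500, seed: int = 0,
                              months: pd.DataFrame | None = None
                              ) -> EffectEstimate | None:
    """Patient-month odds ratio of a favorable response under one drug.

    Exposure = the drug is active that month; favorable depends on the
    outcome ({reduced} short-term, {reduced, freedom_maintained} long-term,
    {freedom_maintained} freedom-only). Drugs used by fewer than
    ``min_patients`` patients are skipped (returns None, logged).
    ``ci="bootstrap"`` replaces the Woolf CI with a patient-level bootstrap.
    """
    if outcome not in FAVORABLE:
        raise ValueError(f"unknown outcome {outcome!r}")
    n_patients = len({e.patient_id for e in cohort.exposures if e.drug == drug})
    if n_patients < min_patients:
        logger.info("skipping %s: used by %d patients (< %d)",
                    drug, n_patients, min_patients)
        return None
    if months is None:
        months = month_response_table(cohort, seizure_type=seizure_type,
                                      sole_exposure=sole_exposure)
    favorable = FAVORABLE[outcome]
    exp = months["exposed_drugs"].apply(lambda s: drug in s)
    fav = months["response_class"].isin(favorable)
    table = [[int((exp & fav).sum()), int((exp & ~fav).sum())],
             [int((~exp & fav).sum()), int((~exp & ~fav).sum())]]
    est = fisher_or(table)
    ci_low, ci_high = est.ci_low, est.ci_high
    if ci == "bootstrap":
        ci_low, ci_high = _bootstrap_ci(months, drug, favorable, n_boot, seed)
    elif ci != "woolf":
        raise ValueError(f"unknown ci method {ci!r}")
    return EffectEstimate(drug=drug, outcome=outcome, table=est.table,
                          or_point=est.or_point, ci_low=ci_low, ci_high=ci_high,
                          p_value=est.p_value, n_patients=n_patients)


def time_locked_response(cohort: Cohort, drug: str | None = None, *,
                         horizon: int = 12,
                         seizure_type: str = OVERALL,
                         spasm_type: str | None = None) -> pd.DataFrame:
    """Percent seizure reduction by month since treatment initiation.

    Patients are aligned at their first initiation month t0 (of ``drug``, or
    of any ASM when ``drug`` is None); reduction(m) = 1 - mean SF(t0+m) /
    mean SF(t0-1) over patients still observed, where the baseline is the
    month before initiation. Patients whose baseline SF is 0 are excluded
    from the ratio (noted in the ``n_excluded_baseline_zero`` attr). When
    ``spasm_type`` is given, a ``spasm_offset_fraction`` column reports the
    cumulative fraction of patients with that seizure type active at
    baseline whose type-specific SF reached 0 by month m post-initiation.
    """
    t0: dict[str, int] = {}
    for e in cohort.exposures:
        if drug is not None and e.drug != drug:
            continue
        t0[e.patient_id] = min(t0.get(e.patient_id, e.start_month), e.start_month)

    baselines, excluded = {}, 0
    for pid, start in t0.items():
        pat = cohort.patients[pid]
        if start - 1 < pat.observation_start_month:
            excluded += 1
            continue
        base = cohort.histories[pid].sf(start - 1, seizure_type)
        if base <= 0:
            excluded += 1
            continue
        baselines[pid] = (start, base)

    spasm_at_risk = {}
    if spasm_type is not None:
        for pid, start in t0.items():
            if cohort.histories[pid].sf(start - 1, spasm_type) > 0 or \
               cohort.histories[pid].sf(start, spasm_type) > 0:
                spasm_at_risk[pid] = start

    rows = []
    for m in range(0, horizon + 1):
        num, den, n = 0.0, 0.0, 0
        for pid, (start, base) in baselines.items():
            month = start + m
            if month > cohort.patients[pid].observation_end_month:
                continue
            num += cohort.histories[pid].sf(month, seizure_type)
            den += base
            n += 1
        row = {"months_since_initiation": m,
               "reduction": (1.0 - num / den) if den > 0 else float("nan"),
               "n": n}
        if spasm_type is not None:
            off, tot = 0, 0
            for pid, start in spasm_at_risk.items():
                end = cohort.patients[pid].observation_end_month
                if start + m > end:
                    continue
                tot += 1
                if any(cohort.histories[pid].sf(start + j, spasm_type) == 0
                       and j > 0 for j in range(1, m + 1)):
                    off += 1
            row["spasm_offset_fraction"] = off / tot if tot else float("nan")
            row["n_spasm"] = tot
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_excluded_baseline_zero"] = excluded
    return out
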