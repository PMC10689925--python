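"""Onset/remission survival analysis and month-wise subgroup comparison.

Seizure onset is the earliest month with a nonzero overall SF score within
the observation window; remission is the first run of at least 12
consecutive seizure-free months beginning after onset (runs truncated by
the end of observation are censored, not counted). Kaplan-Meier estimation
and the log-rank test delegate to lifelines; month-wise comparisons of SF
distributions between subgroups use the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .cohort_model import OVERALL, Cohort, SeizureHistory

__all__ = [
    "KmCurve",
    "RemissionEvent",
    "detect_onset",
    "detect_remission",
    "km_fit",
    "km_quantiles",
    "logrank",
    "monthly_group_comparison",
    "onset_table",
    "remission_table",
]


@dataclass
class KmCurve:
    """Product-limit survival estimate on a monthly time grid."""

    times: np.ndarray            # event/censor times present in the data
    survival: np.ndarray         # S(t) at those times
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s

    def quantile(self, q: float) -> float | None:
        """Smallest t with S(t) <= 1 - q; None if never reached."""
        for ti, si in zip(self.times, self.survival):
            if si <= 1.0 - q + 1e-12:
                return float(ti)
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "month": self.times, "survival": self.survival,
            "at_risk": self.at_risk, "events": self.events,
            "censored": self.censored})


@dataclass(frozen=True)
class RemissionEvent:
    patient_id: str
    offset_month: int      # first month of the qualifying seizure-free run
    qualified: bool
    run_length: int


def detect_onset(history: SeizureHistory, *, seizure_type: str = OVERALL,
                 window: tuple[int, int] | None = None) -> int | None:
    """Earliest month with SF > 0, or None for an all-zero history."""
    series = history.series.get(seizure_type, {})
    months = sorted(m for m, sf in series.items() if sf > 0)
    if window is not None:
        months = [m for m in months if window[0] <= m <= window[1]]
    return months[0] if months else None


def detect_remission(history: SeizureHistory, min_run: int = 12, *,
                     seizure_type: str = OVERALL,
                     anchor: str = "first_free_month") -> RemissionEvent | None:
    """First >=min_run-month seizure-free run after onset, else None.

    A trailing run cut off by the end of observation does not qualify (it is
    censored). ``anchor`` selects the reported offset month:
    ``first_free_month`` (default) or ``last_seizure_month``.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if anchor not in ("first_free_month", "last_seizure_month"):
        raise ValueError(f"unknown anchor {anchor!r}")
    onset = detect_onset(history, seizure_type=seizure_type)
    if onset is None:
        return None
    series = history.series.get(seizure_type, {})
    months = sorted(series)
    last = months[-1]
    run_start, run_len = None, 0
    for m in range(onset + 1, last + 1):
        if series.get(m, 0) == 0:
            if run_start is None:
                run_start = m
            run_len += 1
            if run_len >= min_run:
                offset = run_start if anchor == "first_free_month" else run_start - 1
                # extend to the full observed run length
                full = run_len
                for mm in range(m + 1, last + 1):
                    if series.get(mm, 0) == 0:
                        full += 1
                    else:
                        break
                return RemissionEvent(history.patient_id, offset, True, full)
        else:
            run_start, run_len = None, 0
    return None


def km_fit(event_ages: list[float], censor_ages: list[float]) -> KmCurve:
    """Kaplan-Meier product-limit estimate from event and censoring ages."""
    ages = list(event_ages) + list(censor_ages)
    if not ages:
        raise ValueError("need at least one event or censoring")
    if any(a < 0 for a in ages):
        raise ValueError("ages must be nonnegative")
    observed = [1] * len(event_ages) + [0] * len(censor_ages)
    kmf = KaplanMeierFitter()
    kmf.fit(ages, event_observed=observed)
    table = kmf.event_table  # indexed by time, includes t=0 row
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy()
    keep = times > 0
    return KmCurve(
        times=times[keep], survival=surv[keep],
        at_risk=table["at_risk"].to_numpy()[keep],
        events=table["observed"].to_numpy()[keep],
        censored=table["censored"].to_numpy()[keep])


def km_quantiles(curve: KmCurve,
                 q: tuple[float, ...] = (0.25, 0.5, 0.75, 0.9)
                 ) -> dict[float, float | None]:
    """Survival quantiles; a quantile never reached maps to None."""
    return {qi: curve.quantile(qi) for qi in q}


def logrank(group_a: list[tuple[float, bool]],
            group_b: list[tuple[float, bool]]) -> tuple[float, float]:
    """Two-sample log-rank test on (age, event observed) pairs.

    Returns the chi-square statistic (1 df) and its p-value.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if not any(flag for _, flag in group_a + group_b):
        raise ValueError("no events in either group")
    res = logrank_test(
        [t for t, _ in group_a], [t for t, _ in group_b],
        event_observed_A=[int(f) for _, f in group_a],
        event_observed_B=[int(f) for _, f in group_b])
    return float(res.test_statistic), float(res.p_value)


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; exact when small and tie-free."""
    method = "exact" if (len(x) + len(y) <= 20
                         and len(np.unique(np.concatenate([x, y])))
                         == len(x) + len(y)) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def monthly_group_comparison(cohort: Cohort, grouping: dict[str, list[str]],
                             months: range | list[int], *,
                             seizure_type: str = OVERALL,
                             min_per_group: int = 2,
                             bh_adjust: bool = False) -> pd.DataFrame:
    """Per-month rank-sum comparison of SF distributions between two groups.

    ``grouping`` maps two group names to patient-id lists (e.g. variant
    classes). Months where either group has fewer than ``min_per_group``
    patients under observation are flagged ``tested=False``. Raw p-values
    are reported; ``bh_adjust`` adds a Benjamini-Hochberg column.
    """
    if len(grouping) != 2:
        raise ValueError("grouping must define exactly two groups")
    (name_a, ids_a), (name_b, ids_b) = grouping.items()
    unknown = (set(ids_a) | set(ids_b)) - set(cohort.patients)
    if unknown:
        raise KeyError(f"unknown patient ids in grouping: {sorted(unknown)}")

    frame = cohort.sf_frame(seizure_type)
    rows = []
    for month in months:
        if month not in frame.columns:
            rows.append({"month": month, "tested": False,
                         "statistic": np.nan, "p": np.nan,
                         f"n_{name_a}": 0, f"n_{name_b}": 0})
            continue
        a = frame.loc[frame.index.intersection(ids_a), month].dropna().to_numpy()
        b = frame.loc[frame.index.intersection(ids_b), month].dropna().to_numpy()
        if len(a) < min_per_group or len(b) < min_per_group:
            rows.append({"month": month, "tested": False,
                         "statistic": np.nan, "p": np.nan,
                         f"n_{name_a}": len(a), f"n_{name_b}": len(b)})
            continue
        if np.array_equal(np.sort(a), np.sort(b)) or (
                len(set(a.tolist() + b.tolist())) == 1):
            stat, p = np.nan, 1.0  # identical distributions, nothing to test
        else:
            stat, p = _ranksum_p(a, b)
        rows.append({"month": month, "tested": True, "statistic": stat, "p": p,
                     f"n_{name_a}": len(a), f"n_{name_b}": len(b)})
    out = pd.DataFrame(rows)
    if bh_adjust:
        tested = out["tested"] & out["p"].notna()
        padj = np.full(len(out), np.nan)
        if tested.any():
            padj[tested.to_numpy()] = stats.false_discovery_control(
                out.loc[tested, "p"].to_numpy())
        out["p_bh"] = padj
    return out


# ---------------------------------------------------------------------------
# Cohort-level convenience tables
# ---------------------------------------------------------------------------

def onset_table(cohort: Cohort, *, seizure_type: str = OVERALL) -> pd.DataFrame:
    """Per-patient onset month (NaN when seizure-free) with censoring age."""
    rows = []
    for pid, pat in cohort.patients.items():
        hist = cohort.histories.get(pid, SeizureHistory(pid))
        onset = detect_onset(hist, seizure_type=seizure_type)
        rows.append({"patient_id": pid, "onset_month": onset,
                     "event": onset is not None,
                     "age": onset if onset is not None else pat.observation_end_month,
                     "neonatal": onset == 1,
                     "variant_class": pat.variant_class})
    return pd.DataFrame(rows)


def remission_table(cohort: Cohort, min_run: int = 12, *,
                    seizure_type: str = OVERALL) -> pd.DataFrame:
    """Per-patient remission event/censoring among patients with onset."""
    rows = []
    for pid, pat in cohort.patients.items():
        hist = cohort.histories.get(pid, SeizureHistory(pid))
        onset = detect_onset(hist, seizure_type=seizure_type)
        if onset is None:
            continue
        ev = detect_remission(hist, min_run, seizure_type=seizure_type)
        rows.append({
            "patient_id": pid, "onset_month": onset,
            "event": ev is not None,
            "age": ev.offset_month if ev else pat.observation_end_month,
            "variant_class": pat.variant_class})
    return pd.DataFrame(rows)
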