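"""Longitudinal seizure-frequency forecasting and predictability partition.

The forecasting model predicts each patient's monthly SF trajectory after
the first year of life from the k = 10 patients whose first-year SF series
most closely resemble theirs (mean absolute monthly difference over months
1-12). The predicted score at each month is the per-month median over the
reference patients still under observation. Forecast quality is the mean
absolute divergence between predicted and observed scores; a permutation
test against trajectories of independent uniform random SF scores decides
whether the forecast beats chance, and the cohort is partitioned into
high-fidelity (predictable) and low-fidelity (unpredictable) subgroups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .asm_effectiveness import fisher_or
from .cohort_model import OVERALL, Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "ForecastResult",
    "first_year_distance",
    "similarity_matrix",
    "eligible_first_year",
    "forecast_trajectory",
    "permutation_test",
    "forecast_cohort",
    "partition_fidelity",
    "first_year_risk_features",
]

FIRST_YEAR = range(1, 13)
SF_MAX = 5


@dataclass
class SimilarityMatrix:
    patient_ids: list[str]
    distances: np.ndarray  # symmetric, zero diagonal

    def distance(self, a: str, b: str) -> float:
        ia, ib = self.patient_ids.index(a), self.patient_ids.index(b)
        return float(self.distances[ia, ib])


@dataclass
class ForecastResult:
    patient_id: str
    reference_ids: list[str]
    months: list[int]              # months with both a prediction and an observation
    predicted: list[int]
    observed: list[int]
    divergence: float              # mean absolute predicted-observed difference
    permutation_p: float | None = None
    fidelity: str | None = None    # "high" | "low"
    dropped_months: int = 0        # months with no reference observation
    had_seizures: bool = False     # any nonzero SF anywhere in the history


def first_year_distance(a: list[int] | np.ndarray, b: list[int] | np.ndarray) -> float:
    """Mean absolute monthly SF difference over months 1-12."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != (12,) or b.shape != (12,):
        raise ValueError("first-year vectors must have exactly 12 months")
    return float(np.mean(np.abs(a - b)))


def eligible_first_year(cohort: Cohort, *, seizure_type: str = OVERALL) -> list[str]:
    """Patients whose observation window covers the complete first year."""
    return sorted(
        pid for pid, p in cohort.patients.items()
        if p.observation_start_month <= 1 and p.observation_end_month >= 12)


def similarity_matrix(cohort: Cohort, ids: list[str] | None = None, *,
                      seizure_type: str = OVERALL,
                      metric: str = "mean_abs") -> SimilarityMatrix:
    """Pairwise first-year distances for all eligible patients.

    ``metric``: ``mean_abs`` (default), ``euclidean`` or ``spearman``
    (1 - rank correlation, 0 for degenerate constant series).
    """
    ids = list(ids) if ids is not None else eligible_first_year(cohort)
    mat = np.array([
        cohort.histories[pid].overall_vector(1, 12) for pid in ids], dtype=float)
    if metric == "mean_abs":
        d = np.abs(mat[:, None, :] - mat[None, :, :]).mean(axis=2)
    elif metric == "euclidean":
        d = np.sqrt(((mat[:, None, :] - mat[None, :, :]) ** 2).sum(axis=2))
    elif metric == "spearman":
        from scipy.stats import rankdata
        r = rankdata(mat, axis=1)
        rc = r - r.mean(axis=1, keepdims=True)
        denom = np.sqrt((rc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (rc @ rc.T) / np.outer(denom, denom)
        corr = np.nan_to_num(corr, nan=1.0)
        d = 1.0 - corr
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return SimilarityMatrix(ids, d)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def forecast_trajectory(patient_id: str, cohort: Cohort, *,
                        sim: SimilarityMatrix | None = None,
                        k: int = 10, horizon_cap: int = 60,
                        aggregate: str = "median",
                        seed: int = 0) -> ForecastResult:
    """Predict a patient's post-first-year trajectory from its k nearest
    first-year neighbours.

    Predicted SF at month m > 12 is the median (round-half-up; ``mean`` via
    ``aggregate``) of the reference patients observed at m. Distance ties at
    the reference-set boundary are broken by patient order after a seeded
    shuffle. The horizon is min(patient's last observed month,
    ``horizon_cap``); months where no reference patient is observed are
    dropped from the divergence (counted in ``dropped_months``).
    """
    if sim is None:
        sim = similarity_matrix(cohort)
    ids = sim.patient_ids
    if patient_id not in ids:
        raise KeyError(f"{patient_id!r} is not in the eligible set")
    if len(ids) < 2:
        raise ValueError("need at least one potential reference patient")
    idx = ids.index(patient_id)
    k_eff = min(k, len(ids) - 1)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    cand = [(sim.distances[idx, j], int(order[j]), j)
            for j in range(len(ids)) if j != idx]
    cand.sort()
    reference = [ids[j] for _, _, j in cand[:k_eff]]

    pat = cohort.patients[patient_id]
    horizon = min(pat.observation_end_month, horizon_cap)
    months, predicted, observed = [], [], []
    dropped = 0
    hist = cohort.histories[patient_id]
    for m in range(13, horizon + 1):
        ref_vals = [cohort.histories[r].sf(m) for r in reference
                    if cohort.patients[r].observation_end_month >= m]
        if not ref_vals:
            dropped += 1
            continue
        if aggregate == "median":
            pred = _round_half_up(float(np.median(ref_vals)))
        elif aggregate == "mean":
            pred = _round_half_up(float(np.mean(ref_vals)))
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
        months.append(m)
        predicted.append(pred)
        observed.append(hist.sf(m))
    if dropped:
        logger.info("%s: %d forecast months dropped (no reference observed)",
                    patient_id, dropped)
    divergence = (float(np.mean(np.abs(np.array(predicted) - np.array(observed))))
                  if months else float("nan"))
    had_seizures = any(v > 0 for v in hist.series.get(OVERALL, {}).values())
    return ForecastResult(patient_id, reference, months, predicted, observed,
                          divergence, dropped_months=dropped,
                          had_seizures=had_seizures)


def permutation_test(result: ForecastResult, n_perm: int = 100_000,
                     seed: int = 0, *, null: str = "uniform",
                     cohort: Cohort | None = None) -> float:
    """Better-than-chance test for one forecast.

    The null divergence is the mean absolute difference between the
    *observed* trajectory and a trajectory of SF scores drawn independently
    per month — uniform on {0..5} by default, or resampled from the
    cohort's observed scores at the same month (``null="cohort"``). The
    p-value uses the add-one rule, p = (1 + #{null <= observed}) /
    (n_perm + 1), so it is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not result.months:
        raise ValueError("divergence must be computed over >= 1 month")
    rng = np.random.default_rng(seed)
    obs = np.asarray(result.observed, dtype=float)
    if null == "uniform":
        draws = rng.integers(0, SF_MAX + 1, size=(n_perm, len(obs)))
    elif null == "cohort":
        if cohort is None:
            raise ValueError("cohort required for the cohort-resampling null")
        frame = cohort.sf_frame()
        draws = np.empty((n_perm, len(obs)))
        for j, m in enumerate(result.months):
            pool = frame[m].dropna().to_numpy()
            draws[:, j] = rng.choice(pool, size=n_perm)
    else:
        raise ValueError(f"unknown null {null!r}")
    null_div = np.abs(draws - obs[None, :]).mean(axis=1)
    p = (1 + int(np.sum(null_div <= result.divergence + 1e-12))) / (n_perm + 1)
    result.permutation_p = p
    return p


def forecast_cohort(cohort: Cohort, *, k: int = 10, n_perm: int = 100_000,
                    seed: int = 0, horizon_cap: int = 60,
                    metric: str = "mean_abs",
                    aggregate: str = "median") -> list[ForecastResult]:
    """Forecast + permutation test for every eligible patient."""
    ids = eligible_first_year(cohort)
    sim = similarity_matrix(cohort, ids, metric=metric)
    results = []
    for i, pid in enumerate(ids):
        res = forecast_trajectory(pid, cohort, sim=sim, k=k,
                                  horizon_cap=horizon_cap,
                                  aggregate=aggregate, seed=seed)
        if res.months:
            permutation_test(res, n_perm=n_perm, seed=seed + 1 + i)
        results.append(res)
    return results


def partition_fidelity(results: list[ForecastResult], *,
                       alpha: float = 0.05,
                       divergence_quantile: float = 2 / 3,
                       divergence_threshold: float | None = None
                       ) -> pd.DataFrame:
    """Label each forecast high- or low-fidelity.

    Low fidelity means the forecast is not better than chance
    (permutation p >= alpha) OR the divergence exceeds a threshold —
    by default the cohort's 66.7th percentile of divergence among patients
    with any observed seizures. Patients who never seized and were
    correctly forecast all-zero are high fidelity by construction.
    """
    if not results:
        raise ValueError("empty result set")
    scored = [r for r in results if r.months]
    seizing_div = [r.divergence for r in scored if r.had_seizures]
    if divergence_threshold is None:
        divergence_threshold = (float(np.quantile(seizing_div, divergence_quantile))
                                if seizing_div else 0.0)
    rows = []
    for r in results:
        if not r.months:
            rows.append({"patient_id": r.patient_id, "fidelity": "unscored",
                         "divergence": r.divergence, "permutation_p": None})
            continue
        low = ((r.permutation_p is not None and r.permutation_p >= alpha)
               or r.divergence > divergence_threshold + 1e-12)
        r.fidelity = "low" if low else "high"
        rows.append({"patient_id": r.patient_id, "fidelity": r.fidelity,
                     "divergence": r.divergence,
                     "permutation_p": r.permutation_p})
    out = pd.DataFrame(rows)
    out.attrs["divergence_threshold"] = divergence_threshold
    return out


# ---------------------------------------------------------------------------
# First-year features enriched in the low-fidelity subgroup
# ---------------------------------------------------------------------------

def _max_consecutive_seizure_months(sf: list[int]) -> int:
    best = cur = 0
    for v in sf:
        cur = cur + 1 if v > 0 else 0
        best = max(best, cur)
    return best


def first_year_features(cohort: Cohort, patient_id: str, *,
                        consecutive_threshold: int = 6) -> dict[str, bool]:
    """Binary first-year seizure-history features for one patient."""
    hist = cohort.histories[patient_id]
    sf12 = hist.overall_vector(1, 12)
    from .synthetic_cohort import HP_SPASMS  # HPO CURIE constant only
    spasm_months = [m for m, v in hist.series.get(HP_SPASMS, {}).items() if v > 0]
    return {
        "ongoing_at_month_12": sf12[11] > 0,
        "offset_by_month_7": (any(v > 0 for v in sf12[:7])
                              and all(v == 0 for v in sf12[7:])),
        "spasms_after_month_6": any(m > 6 for m in spasm_months),
        "long_consecutive_run": _max_consecutive_seizure_months(sf12)
                                > consecutive_threshold,
    }


def first_year_risk_features(cohort: Cohort, labels: pd.DataFrame, *,
                             consecutive_threshold: int = 6) -> pd.DataFrame:
    """Fisher's-exact odds of low-fidelity membership per first-year feature.

    Degenerate (constant) features are reported with OR = NaN and a note;
    features perfectly aligned with the label get an infinite OR estimate
    before correction and are flagged.
    """
    lab = labels[labels["fidelity"].isin(["high", "low"])]
    rows = []
    for feature in ("ongoing_at_month_12", "offset_by_month_7",
                    "spasms_after_month_6", "long_consecutive_run"):
        table = np.zeros((2, 2), dtype=int)
        for _, rec in lab.iterrows():
            feats = first_year_features(cohort, rec["patient_id"],
                                        consecutive_threshold=consecutive_threshold)
            i = 0 if feats[feature] else 1
            j = 0 if rec["fidelity"] == "low" else 1
            table[i, j] += 1
        if table[0].sum() == 0 or table[1].sum() == 0:
            rows.append({"feature": feature, "or": float("nan"), "ci_low": None,
                         "ci_high": None, "p": None, "note": "degenerate feature"})
            continue
        est = fisher_or(table)
        note = ""
        if table[0, 1] == 0 or table[1, 0] == 0:
            note = "zero cell; Haldane-Anscombe corrected"
        rows.append({"feature": feature, "or": est.or_point,
                     "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "p": est.p_value, "note": note})
    return pd.DataFrame(rows)
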