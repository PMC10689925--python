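"""Virtual clinical trial simulation and the OFTS curve.

Each virtual trial samples up to 20 patients with ongoing seizures at the
trial start month, applies a simulated multiplicative seizure reduction to
their observed monthly SF scores over a 6- or 12-month window (kept on a
continuous scale), and evaluates the injected effect against the same
patients' observed scores — a synthetic-control design in which the
cohort's own recorded histories serve as the comparator arm rather than a
placebo group. The default evaluation is a one-sided Wilcoxon signed-rank
test on per-patient cumulative window SF (treated vs observed); an
unpaired rank-sum mode is available. The Observed Frequency of Trial
Success (OFTS) at a start month is the proportion of simulated trials
reaching significance.

The signed-rank tail probability is computed exactly for n <= 25 via the
tie-aware rank-sum distribution (dynamic programming over mid-ranks),
falling back to the normal approximation with tie correction for larger n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import OVERALL, Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "TrialConfig",
    "TrialResult",
    "OftsCurve",
    "signed_rank_p_less",
    "eligible_patients",
    "run_trial",
    "ofts",
]


@dataclass(frozen=True)
class TrialConfig:
    start_month: int = 12
    duration: int = 6                  # months; the study grid is {6, 12}
    reduction: float = 0.20           # fractional SF reduction in [0, 1]
    n_subjects: int = 20
    n_trials: int = 1000
    alpha: float = 0.05
    min_eligible: int = 5
    seizure_type: str = OVERALL
    test: str = "signed_rank"          # or "rank_sum"
    ordinal_rounding: bool = False     # re-round treated scores to {0..5}
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.reduction <= 1.0):
            raise ValueError("reduction must be in [0, 1]")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.duration < 1:
            raise ValueError("duration must be >= 1")


@dataclass
class TrialResult:
    p_value: float
    success: bool
    n_sampled: int


@dataclass
class OftsCurve:
    duration: int
    reduction: float
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: start_month, duration, reduction, n_eligible, trials_run, ofts
    # months with too few eligible patients have trials_run 0 and ofts NaN


def signed_rank_p_less(treated: np.ndarray, control: np.ndarray, *,
                       exact_max_n: int = 25) -> float:
    """One-sided Wilcoxon signed-rank p for H1: treated < control.

    Zero differences are dropped (Wilcoxon's rule); ties in |d| receive
    mid-ranks. For n <= exact_max_n the tail probability
    P(W+ <= w_obs) is computed exactly by enumerating the distribution of
    the positive-rank sum over all 2^n sign assignments via dynamic
    programming, which remains exact under ties — identical differences in
    the same direction still give the minimal one-sided p of 2^-n.
    """
    d = np.asarray(treated, dtype=float) - np.asarray(control, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))          # mid-ranks; multiples of 0.5
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        scaled = np.round(ranks * 2).astype(int)   # integers; total <= n(n+1)
        total = int(scaled.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in scaled:
            counts[r:] += counts[:total + 1 - r].copy()
        w_scaled = int(round(w_plus * 2))
        return float(counts[: w_scaled + 1].sum() / 2.0 ** n)
    # normal approximation with tie correction
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = (n * (n + 1) * (2 * n + 1) - (tie_counts ** 3 - tie_counts).sum() / 2) / 24.0
    z = (w_plus + 0.5 - mu) / np.sqrt(var)
    return float(stats.norm.cdf(z))


def eligible_patients(cohort: Cohort, start_month: int, *,
                      duration: int = 6,
                      seizure_type: str = OVERALL) -> list[str]:
    """Patients with ongoing seizures at the start month and observation
    extending at least ``duration`` months beyond it."""
    out = []
    for pid, pat in cohort.patients.items():
        if not (pat.observation_start_month <= start_month
                and pat.observation_end_month >= start_month + duration):
            continue
        if cohort.histories[pid].sf(start_month, seizure_type) > 0:
            out.append(pid)
    return sorted(out)


def _window_sf(cohort: Cohort, pid: str, start: int, duration: int,
               seizure_type: str) -> np.ndarray:
    h = cohort.histories[pid]
    return np.array([h.sf(start + j, seizure_type) for j in range(duration + 1)],
                    dtype=float)


def run_trial(cohort: Cohort, config: TrialConfig,
              rng: np.random.Generator | None = None, *,
              eligible: list[str] | None = None) -> TrialResult | None:
    """One virtual trial; None when fewer than min_eligible patients exist.

    The treated series is each sampled patient's observed window scaled by
    (1 - reduction); success means the one-sided test on per-patient
    cumulative window SF rejects at alpha.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if eligible is None:
        eligible = eligible_patients(cohort, config.start_month,
                                     duration=config.duration,
                                     seizure_type=config.seizure_type)
    if len(eligible) < config.min_eligible:
        return None
    n = min(config.n_subjects, len(eligible))
    if n < len(eligible):
        sample = list(rng.choice(eligible, size=n, replace=False))
    else:
        sample = list(eligible)
        logger.debug("pool of %d used whole at month %d", n, config.start_month)

    control = np.array([
        _window_sf(cohort, pid, config.start_month, config.duration,
                   config.seizure_type).sum() for pid in sample])
    factor = 1.0 - config.reduction
    if config.ordinal_rounding:
        treated = np.array([
            np.floor(_window_sf(cohort, pid, config.start_month, config.duration,
                                config.seizure_type) * factor + 0.5).sum()
            for pid in sample])
    else:
        treated = control * factor

    if config.test == "signed_rank":
        p = signed_rank_p_less(treated, control)
    elif config.test == "rank_sum":
        if np.all(treated == treated[0]) and np.all(control == control[0]) \
                and treated[0] == control[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(treated, control,
                                         alternative="less").pvalue)
    else:
        raise ValueError(f"unknown test {config.test!r}")
    return TrialResult(p_value=p, success=p < config.alpha, n_sampled=n)


def ofts(cohort: Cohort, months: range | list[int],
         config: TrialConfig | None = None, *,
         durations: tuple[int, ...] | None = None,
         reductions: tuple[float, ...] | None = None) -> list[OftsCurve]:
    """OFTS curves over start months for a (duration, reduction) grid.

    For each grid cell and start month, ``n_trials`` independently sampled
    trials are run; OFTS = successes / trials run. Months with too few
    eligible patients are reported with ``ofts`` NaN (never zero-filled),
    and the eligible-pool size is carried so that repeated-sampling
    artefacts in sparse windows stay visible.
    """
    base = config or TrialConfig()
    durations = durations or (base.duration,)
    reductions = reductions or (base.reduction,)
    curves = []
    for duration in durations:
        for reduction in reductions:
            cfg = replace(base, duration=duration, reduction=reduction)
            rows = []
            for start in months:
                cfg_m = replace(cfg, start_month=start)
                pool = eligible_patients(cohort, start, duration=duration,
                                         seizure_type=cfg.seizure_type)
                rng = np.random.default_rng(
                    (cfg.seed, duration, int(reduction * 1000), start))
                successes, run = 0, 0
                if len(pool) >= cfg.min_eligible:
                    for _ in range(cfg.n_trials):
                        res = run_trial(cohort, cfg_m, rng, eligible=pool)
                        run += 1
                        successes += int(res.success)
                rows.append({"start_month": start, "duration": duration,
                             "reduction": reduction, "n_eligible": len(pool),
                             "trials_run": run,
                             "ofts": successes / run if run else float("nan")})
            curves.append(OftsCurve(duration, reduction, pd.DataFrame(rows)))
    return curves
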