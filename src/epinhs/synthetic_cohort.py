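"""Seeded synthetic-cohort generator.

Emulates the statistical structure of a rare genetic developmental and
epileptic encephalopathy cohort so that every downstream analysis stage is
testable without access to clinical data: ~71% epilepsy prevalence with a
neonatal-onset subgroup, variant-class-specific seizure signatures
(protein-truncating variants/deletions: an infantile-spasm peak at months
5-6 followed by remission; missense variants: persistent focal seizures in
months 10-24), remission as >=12-month seizure-free runs, anti-seizure
medication exposures with configurable true effect multipliers, and
milestone ages coupled to onset severity.

Monthly seizure-frequency dynamics are a per-patient Markov chain on the
ordinal SF scale {0..5} with subgroup-specific persistence, overlaid with an
active/remitted state machine (remission entry hazard, relapse hazard).
Drug effects act on the dynamics while exposed: a drug with multiplier m
tilts the monthly SF transition distribution downward in proportion to 1-m
(plus a one-off step-down at initiation), and freedom-maintenance agents
multiply the post-remission relapse hazard by their freedom factor.

Every latent draw (true onset, subgroup, spasm episode, per-month latent SF
and applied effect, true milestone ages) is returned in a ``GroundTruth``
record for parameter-recovery tests. Analysis modules never read the ground
truth; the separation is enforced by keeping it out of the ``Cohort``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort_model import (
    OVERALL,
    AsmExposure,
    AssessmentRecord,
    Cohort,
    MilestoneRecord,
    Patient,
    SeizureHistory,
    validate,
)

__all__ = [
    "HP_SPASMS",
    "HP_FOCAL",
    "AsmEffect",
    "MilestoneSpec",
    "GeneratorConfig",
    "GroundTruth",
    "generate_cohort",
    "inject_predictability_structure",
]

#: HPO CURIEs used for the two structurally modelled seizure types.
HP_SPASMS = "HP:0012469"   # infantile spasms
HP_FOCAL = "HP:0007359"    # focal-onset seizures


@dataclass(frozen=True)
class AsmEffect:
    """True treatment effect for one drug.

    sf_multiplier < 1 injects short-term seizure reduction; freedom_factor
    < 1 scales the post-remission relapse hazard (long-term freedom
    maintenance).
    """

    sf_multiplier: float = 1.0
    freedom_factor: float = 1.0


@dataclass(frozen=True)
class MilestoneSpec:
    """Base lognormal age-at-acquisition plus an onset-severity shift."""

    median_months: float
    log_sigma: float
    achieve_prob: float            # later/no epilepsy stratum
    achieve_prob_neonatal: float   # neonatal-onset stratum
    neonatal_delay_months: float   # additive age shift for neonatal onset


def _default_asm_effects() -> dict[str, AsmEffect]:
    return {
        "phenobarbital": AsmEffect(0.50, 1.0),
        "levetiracetam": AsmEffect(0.90, 1.0),
        "topiramate": AsmEffect(0.85, 0.80),
        "acth": AsmEffect(0.60, 1.0),
        "vigabatrin": AsmEffect(0.70, 1.0),
        "clobazam": AsmEffect(0.90, 0.40),
        "ketogenic_diet": AsmEffect(0.95, 0.55),
    }


def _default_milestone_model() -> dict[str, MilestoneSpec]:
    return {
        "head_control": MilestoneSpec(6.3, 0.50, 0.95, 0.75, 4),
        "roll_over": MilestoneSpec(7.6, 0.45, 0.93, 0.80, 3),
        "sit_unassisted": MilestoneSpec(12.0, 0.45, 0.80, 0.55, 4),
        "grasp": MilestoneSpec(10.0, 0.50, 0.85, 0.60, 3),
        "walk": MilestoneSpec(29.0, 0.50, 0.68, 0.30, 6),
        "walk_unassisted": MilestoneSpec(29.0, 0.50, 0.68, 0.25, 6),
        "first_words": MilestoneSpec(24.0, 0.60, 0.43, 0.12, 6),
        "nonverbal_communication": MilestoneSpec(18.0, 0.50, 1.0, 1.0, 0),
    }


@dataclass
class GeneratorConfig:
    """All tunable generator parameters; defaults are the study conditions.

    The onset distribution for non-neonatal onset is a discretized
    lognormal, 1 + round(exp(N(mu, sigma))), with (mu, sigma) = (1.82, 1.20)
    calibrated so that the *overall* onset quantiles among epileptic
    patients approximate 25th neonatal / median 2 months / 75th 7 months /
    90th ~1.6 years once the neonatal point mass is included.
    """

    n_patients: int = 101
    seed: int = 0
    epilepsy_fraction: float = 0.71              # ~= 72/101
    neonatal_fraction_among_epilepsy: float = 31 / 72
    onset_lognormal_mu: float = 1.82
    onset_lognormal_sigma: float = 1.20
    variant_mix: dict[str, float] = field(default_factory=lambda: {
        "ptv_del": 0.53, "missense": 0.44, "inframe_indel": 0.03})
    # observation (censoring) age: lognormal, median ~5.1 years
    obs_end_median_months: float = 61.0
    obs_end_log_sigma: float = 0.85
    obs_end_min_months: int = 18
    obs_end_max_months: int = 240
    # seizure dynamics
    ptv_spasm_window: tuple[int, int] = (5, 6)
    ptv_spasm_hazard: float = 0.60               # P(spasm episode | epileptic PTV/del)
    missense_focal_window: tuple[int, int] = (10, 24)
    missense_persistence: float = 0.85           # P(focal seizure month | active, in window)
    markov_stay_prob: dict[str, float] = field(default_factory=lambda: {
        "ptv_del": 0.80, "missense": 0.78, "inframe_indel": 0.78})
    remission_hazard: dict[str, float] = field(default_factory=lambda: {
        "ptv_del": 0.02, "missense": 0.030, "inframe_indel": 0.06})
    post_spasm_remission_hazard: float = 0.30    # PTV/del hazard after the spasm window
    missense_window_hazard_factor: float = 0.30  # hazard damping during focal window
    relapse_hazard: float = 0.04                 # monthly, after remission
    asm_effects: dict[str, AsmEffect] = field(default_factory=_default_asm_effects)
    #: drug -> (probability, min/max duration months); exposure windows are
    #: placed uniformly at random over the patient's observation span,
    #: independent of covariates (for randomized effect-recovery designs)
    randomized_exposures: dict[str, tuple[float, int, int]] = field(
        default_factory=dict)
    milestone_model: dict[str, MilestoneSpec] = field(
        default_factory=_default_milestone_model)
    generate_milestones: bool = True
    generate_assessments: bool = True
    generate_exposures: bool = True

    def validate(self) -> None:
        probs = [self.epilepsy_fraction, self.neonatal_fraction_among_epilepsy,
                 self.ptv_spasm_hazard, self.missense_persistence,
                 self.relapse_hazard, *self.remission_hazard.values(),
                 *self.markov_stay_prob.values()]
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0,1]: {p}")
        total = sum(self.variant_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variant_mix must sum to 1, got {total}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.epilepsy_fraction == 0.0 and self.ptv_spasm_hazard > 0.0:
            # spasm episodes are a property of epileptic patients only; a
            # nonzero spasm hazard with no epilepsy is contradictory
            raise ValueError(
                "infeasible config: epilepsy_fraction 0 with nonzero spasm hazard")


@dataclass
class GroundTruth:
    """Latent draws behind a generated cohort (for recovery tests only)."""

    seed: int
    patients: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "patients": self.patients}, indent=2, sort_keys=True))


def _draw_onset(rng: np.random.Generator, cfg: GeneratorConfig, obs_end: int) -> tuple[int, bool]:
    neonatal = rng.random() < cfg.neonatal_fraction_among_epilepsy
    if neonatal:
        return 1, True
    onset = 1 + int(round(math.exp(rng.normal(
        cfg.onset_lognormal_mu, cfg.onset_lognormal_sigma))))
    onset = max(2, min(onset, obs_end))
    return onset, False


def _simulate_epilepsy(rng: np.random.Generator, cfg: GeneratorConfig,
                       variant: str, onset: int, obs_end: int,
                       exposures: list[AsmExposure]) -> dict:
    """Month-by-month SF simulation for one epileptic patient.

    Returns latent/observed overall SF vectors, per-type series and
    per-month applied effect multipliers.
    """
    stay = cfg.markov_stay_prob.get(variant, 0.78)
    spasm_lo, spasm_hi = cfg.ptv_spasm_window
    foc_lo, foc_hi = cfg.missense_focal_window

    has_spasms = (variant == "ptv_del" and onset <= spasm_hi
                  and rng.random() < cfg.ptv_spasm_hazard)

    effects = cfg.asm_effects

    def month_multipliers(m: int) -> tuple[float, float]:
        sf_mult, freedom = 1.0, 1.0
        for e in exposures:
            if e.covers(m):
                eff = effects.get(e.drug, AsmEffect())
                sf_mult *= eff.sf_multiplier
                freedom *= eff.freedom_factor
        return sf_mult, freedom

    observed = np.zeros(obs_end + 1, dtype=int)   # index = month of life
    multipliers = np.ones(obs_end + 1, dtype=float)
    spasm_series: dict[int, int] = {}
    focal_series: dict[int, int] = {}

    state = "pre"
    level = 0
    remission_entry = None
    prev_mult = 1.0
    for m in range(1, obs_end + 1):
        sf_mult, freedom = month_multipliers(m)
        multipliers[m] = sf_mult

        if state == "pre" and m >= onset:
            state = "active"
            # presentations start as low-to-moderate-grade seizures in both
            # variant classes; the 5-6 month PTV/del contrast comes from the
            # spasm episode itself, the later missense contrast from the
            # persistent focal window
            level = int(rng.choice([1, 2, 3, 4], p=[0.30, 0.35, 0.25, 0.10]))

        if state == "active":
            # subgroup-specific remission hazard
            hazard = cfg.remission_hazard.get(variant, 0.04)
            if variant == "ptv_del" and m > spasm_hi:
                hazard = cfg.post_spasm_remission_hazard
            if variant == "missense" and foc_lo <= m <= foc_hi:
                hazard *= cfg.missense_window_hazard_factor
            if rng.random() < hazard:
                state = "remitted"
                remission_entry = remission_entry or m
                level = 0
            else:
                # ordinal random walk with persistence; an active drug tilts
                # the move distribution downward in proportion to 1 - mult
                move = 1.0 - stay
                p_down = move * (0.5 + 0.5 * (1.0 - sf_mult))
                u = rng.random()
                if u < p_down:
                    level = max(1, level - 1)
                elif u < move:
                    level = min(5, level + 1)
                # initiation response: a newly started drug steps SF down
                if sf_mult < prev_mult and rng.random() < (1.0 - sf_mult):
                    level = max(1, level - 1)
        elif state == "remitted":
            if rng.random() < cfg.relapse_hazard * freedom:
                state = "active"
                level = int(rng.choice([1, 2, 3]))

        observed[m] = level if state == "active" else 0

        # structural type signatures override the walk while active
        if state == "active":
            if has_spasms and spasm_lo <= m <= spasm_hi:
                s = int(rng.choice([4, 5]))
                spasm_series[m] = s
                observed[m] = max(int(observed[m]), s)
            if (variant == "missense" and foc_lo <= m <= foc_hi
                    and rng.random() < cfg.missense_persistence):
                f = max(int(observed[m]), 2)
                focal_series[m] = f
                observed[m] = f
            elif onset == 1 and m <= 3 and observed[m] > 0:
                focal_series[m] = int(observed[m])  # neonatal seizures mostly focal
        prev_mult = sf_mult

    spasm_obs = {m: min(v, int(observed[m])) for m, v in spasm_series.items()
                 if min(v, int(observed[m])) > 0}
    focal_obs = {m: min(v, int(observed[m])) for m, v in focal_series.items()
                 if min(v, int(observed[m])) > 0}
    return {
        "observed": observed, "multipliers": multipliers,
        "spasms": spasm_obs, "focal": focal_obs, "has_spasms": has_spasms,
        "remission_entry": remission_entry,
    }


def _assign_exposures(rng: np.random.Generator, cfg: GeneratorConfig,
                      pid: str, variant: str, onset: int, obs_end: int,
                      neonatal: bool, may_have_spasms: bool) -> list[AsmExposure]:
    def clip(start: int, end: int) -> tuple[int, int] | None:
        start, end = max(1, start), min(obs_end, end)
        return (start, end) if start <= end else None

    out: list[AsmExposure] = []

    def add(drug: str, start: int, end: int, prob: float) -> None:
        if rng.random() < prob:
            iv = clip(start, end)
            if iv:
                out.append(AsmExposure(pid, drug, iv[0], iv[1]))

    if neonatal:
        add("phenobarbital", 1, 4, 0.85)
    if may_have_spasms:
        add("acth", cfg.ptv_spasm_window[0], cfg.ptv_spasm_window[1] + 1, 0.70)
        add("vigabatrin", cfg.ptv_spasm_window[0], cfg.ptv_spasm_window[1] + 3, 0.60)
    add("levetiracetam", onset, onset + 30, 0.65)
    add("topiramate", max(onset + 3, 6), max(onset + 3, 6) + 18, 0.35)
    if obs_end >= 30:
        add("clobazam", 24, 54, 0.35)
    if obs_end >= 36:
        add("ketogenic_diet", 30, 54, 0.20)
    return out


def _generate_milestones(rng: np.random.Generator, cfg: GeneratorConfig,
                         pid: str, neonatal_onset: bool, obs_end: int
                         ) -> tuple[list[MilestoneRecord], dict]:
    records, truth = [], {}
    for name, spec in cfg.milestone_model.items():
        p = spec.achieve_prob_neonatal if neonatal_onset else spec.achieve_prob
        would_achieve = rng.random() < p
        age = math.exp(rng.normal(math.log(spec.median_months), spec.log_sigma))
        if neonatal_onset:
            age += spec.neonatal_delay_months
        age = round(age, 1)
        truth[name] = {"would_achieve": would_achieve, "true_age_months": age}
        if would_achieve and age <= obs_end:
            records.append(MilestoneRecord(pid, name, True, age, float(obs_end)))
        else:
            records.append(MilestoneRecord(pid, name, False, None, float(obs_end)))
    return records, truth


_GMFCS_P = [0.12, 0.39, 0.10, 0.27, 0.12]
_MACS_P = [0.02, 0.42, 0.22, 0.22, 0.12]
_CFCS_P = [0.02, 0.05, 0.13, 0.21, 0.59]
_LEVELS = ["I", "II", "III", "IV", "V"]


def _gmfm_mean(age_months: float) -> float:
    # saturating growth: ~26 at 6 months, ~42 at 2 years, ~58 past 5 years
    return 18.0 + 45.0 * (1.0 - math.exp(-age_months / 28.0))


def _generate_assessments(rng: np.random.Generator, pid: str, obs_end: int,
                          neonatal_onset: bool) -> list[AssessmentRecord]:
    out: list[AssessmentRecord] = []
    shift = -6.0 if neonatal_onset else 0.0
    if rng.random() < 0.45:
        for _ in range(int(rng.integers(1, 3))):
            age = float(rng.integers(6, max(7, obs_end)))
            score = float(np.clip(rng.normal(_gmfm_mean(age) + shift, 8.0), 0, 100))
            out.append(AssessmentRecord(pid, "gmfm66is", age, round(score, 1)))
    if rng.random() < 0.20:
        age = float(rng.integers(12, max(13, min(obs_end, 60))))
        for scale in ("pdms2_grasping", "pdms2_vmi"):
            score = float(np.clip(rng.normal(33 + shift, 10.0), 0, 100))
            out.append(AssessmentRecord(pid, scale, age, round(score, 1)))
    for scale, probs, rate in (("gmfcs_er", _GMFCS_P, 0.40),
                               ("macs", _MACS_P, 0.10),
                               ("cfcs", _CFCS_P, 0.20)):
        if rng.random() < rate:
            age = float(rng.integers(18, max(19, obs_end)))
            lvl = _LEVELS[int(rng.choice(5, p=probs))]
            out.append(AssessmentRecord(pid, scale, age, lvl))
    return out


def generate_cohort(config: GeneratorConfig | None = None) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort plus the ground truth behind every latent draw.

    Identical ``config`` (including its ``seed``) yields a byte-identical
    serialized cohort.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    cohort = Cohort(provenance={"source": "synthetic", "seed": cfg.seed})
    truth = GroundTruth(seed=cfg.seed)

    variant_names = sorted(cfg.variant_mix)
    variant_p = np.array([cfg.variant_mix[v] for v in variant_names])

    for i in range(cfg.n_patients):
        pid = f"P{i:04d}"
        sex = "male" if rng.random() < 0.5 else "female"
        variant = variant_names[int(rng.choice(len(variant_names), p=variant_p))]
        obs_end = int(np.clip(round(math.exp(rng.normal(
            math.log(cfg.obs_end_median_months), cfg.obs_end_log_sigma))),
            cfg.obs_end_min_months, cfg.obs_end_max_months))
        has_epilepsy = rng.random() < cfg.epilepsy_fraction

        pt_truth: dict = {"variant_class": variant, "has_epilepsy": has_epilepsy,
                          "obs_end": obs_end}
        hist = SeizureHistory(pid)
        exposures: list[AsmExposure] = []

        if has_epilepsy:
            onset, neonatal = _draw_onset(rng, cfg, obs_end)
            may_have_spasms = variant == "ptv_del" and onset <= cfg.ptv_spasm_window[1]
            if cfg.generate_exposures:
                exposures = _assign_exposures(rng, cfg, pid, variant, onset,
                                              obs_end, neonatal, may_have_spasms)
            for drug, (prob, dmin, dmax) in cfg.randomized_exposures.items():
                if rng.random() < prob:
                    dur = int(rng.integers(dmin, dmax + 1))
                    start = int(rng.integers(1, max(2, obs_end - dur + 1)))
                    exposures.append(AsmExposure(pid, drug, start,
                                                 min(obs_end, start + dur - 1)))
            sim = _simulate_epilepsy(rng, cfg, variant, onset, obs_end, exposures)
            hist.series[OVERALL] = {m: int(sim["observed"][m])
                                    for m in range(1, obs_end + 1)}
            if sim["spasms"]:
                hist.series[HP_SPASMS] = sim["spasms"]
            if sim["focal"]:
                hist.series[HP_FOCAL] = sim["focal"]
            pt_truth.update({
                "onset_month": onset, "neonatal_onset": neonatal,
                "has_spasms": sim["has_spasms"],
                "remission_entry": sim["remission_entry"],
                "sf": [int(x) for x in sim["observed"][1:]],
                "effect_multiplier": [float(x) for x in sim["multipliers"][1:]],
            })
            neonatal_onset = neonatal
        else:
            hist.series[OVERALL] = {m: 0 for m in range(1, obs_end + 1)}
            pt_truth.update({"onset_month": None, "neonatal_onset": False,
                             "has_spasms": False, "remission_entry": None})
            neonatal_onset = False

        if cfg.generate_milestones:
            records, ms_truth = _generate_milestones(rng, cfg, pid,
                                                     neonatal_onset, obs_end)
            cohort.milestones.extend(records)
            pt_truth["milestones"] = ms_truth
        if cfg.generate_assessments:
            cohort.assessments.extend(
                _generate_assessments(rng, pid, obs_end, neonatal_onset))

        cohort.patients[pid] = Patient(
            patient_id=pid, sex=sex, variant_class=variant, variant_label="",
            observation_start_month=1, observation_end_month=obs_end,
            has_epilepsy=has_epilepsy)
        cohort.histories[pid] = hist
        cohort.exposures.extend(exposures)
        truth.patients[pid] = pt_truth

    validate(cohort)
    return cohort, truth


def inject_predictability_structure(
        cohort: Cohort, fraction_predictable: float, seed: int | None = None
) -> tuple[Cohort, dict[str, str]]:
    """Overwrite epileptic patients' trajectories with known predictability.

    A fixed fraction (rounded to a count) of epileptic patients receives an
    early-offset pattern — seizures in the first months resolving by month
    7, all-zero thereafter — and the remainder receive refractory
    high-variance patterns with random month-to-month SF (uniform on {1..5},
    hence ongoing seizures at month 12). Returns the modified cohort and the
    ground-truth label per epileptic patient.
    """
    if not (0.0 <= fraction_predictable <= 1.0):
        raise ValueError("fraction_predictable must be in [0, 1]")
    if seed is None:
        seed = int(cohort.provenance.get("seed", 0)) + 1
    rng = np.random.default_rng(seed)

    epileptic = sorted(pid for pid, p in cohort.patients.items() if p.has_epilepsy)
    n_pred = int(round(fraction_predictable * len(epileptic)))
    order = list(rng.permutation(len(epileptic)))
    predictable = {epileptic[j] for j in order[:n_pred]}

    labels: dict[str, str] = {}
    for pid in epileptic:
        pat = cohort.patients[pid]
        end = pat.observation_end_month
        hist = cohort.histories[pid]
        series: dict[int, int] = {m: 0 for m in range(1, end + 1)}
        if pid in predictable:
            labels[pid] = "predictable"
            stop = min(7, end)
            for m in range(2, stop + 1):
                series[m] = int(rng.integers(2, 5))  # resolves by month 7
        else:
            labels[pid] = "unpredictable"
            for m in range(1, end + 1):
                series[m] = int(rng.integers(1, 6))  # ongoing, high variance
        hist.series = {OVERALL: series}
    cohort.provenance["predictability_truth"] = dict(labels)
    return cohort, labels


def config_to_dict(cfg: GeneratorConfig) -> dict:
    """JSON-serializable dump of a config (for provenance records)."""
    d = dataclasses.asdict(cfg)
    d["asm_effects"] = {k: dataclasses.asdict(v) for k, v in cfg.asm_effects.items()}
    d["milestone_model"] = {k: dataclasses.asdict(v)
                            for k, v in cfg.milestone_model.items()}
    return d
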