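"""Core cohort data model for longitudinal seizure-frequency histories.

A cohort is a set of patients observed over closed month-of-life intervals
(1-based; month 1 is the neonatal month). Each patient carries one ordinal
seizure-frequency (SF) score per month of life, overall and optionally per
seizure type (seizure types are tagged with HPO term identifiers). The SF
scale is ordinal 0-5:

    5  >5 seizures per day
    4  2-5 seizures per day
    3  daily seizures
    2  weekly seizures
    1  monthly seizures
    0  no seizures

Months in which seizures were documented as present but with unknown
frequency are held as an explicit UNKNOWN_PRESENT marker until
:func:`impute_unknown_present` replaces them with the cohort median for the
respective month.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SF_DESCRIPTORS",
    "SF_LABELS",
    "UNKNOWN_PRESENT",
    "OVERALL",
    "CohortValidationError",
    "Patient",
    "SeizureHistory",
    "AsmExposure",
    "MilestoneRecord",
    "AssessmentRecord",
    "Cohort",
    "encode_sf",
    "decode_sf",
    "impute_unknown_present",
    "validate",
    "read_cohort",
    "write_cohort",
    "canonical_frames",
]

#: Bijection between frequency descriptors and ordinal SF scores.
SF_DESCRIPTORS: dict[str, int] = {
    ">5/day": 5,
    "2-5/day": 4,
    "daily": 3,
    "weekly": 2,
    "monthly": 1,
    "none": 0,
}
SF_LABELS: dict[int, str] = {v: k for k, v in SF_DESCRIPTORS.items()}

#: In-memory sentinel for "seizures present, frequency unknown".
UNKNOWN_PRESENT: int = -1
#: CSV spelling of the sentinel.
UNKNOWN_PRESENT_TOKEN = "present_unknown"

#: Sentinel seizure-type key for the overall (any-type) SF series.
OVERALL = "overall"

VALID_SEXES = frozenset({"male", "female", "unknown"})
VALID_VARIANT_CLASSES = frozenset({"missense", "ptv_del", "inframe_indel", "unknown"})


class CohortValidationError(ValueError):
    """Aggregated validation failure; ``errors`` lists every offence found."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "cohort validation failed with %d error(s):\n  %s"
            % (len(errors), "\n  ".join(errors))
        )


def encode_sf(frequency_descriptor: str) -> int:
    """Map a monthly seizure-frequency descriptor to its ordinal SF score."""
    try:
        return SF_DESCRIPTORS[frequency_descriptor]
    except KeyError:
        raise CohortValidationError(
            [f"unrecognized seizure-frequency descriptor: {frequency_descriptor!r} "
             f"(expected one of {sorted(SF_DESCRIPTORS)})"]
        ) from None


def decode_sf(score: int) -> str:
    """Inverse of :func:`encode_sf`."""
    try:
        return SF_LABELS[score]
    except KeyError:
        raise CohortValidationError([f"SF score out of range: {score!r}"]) from None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: str = "unknown"
    variant_class: str = "unknown"
    variant_label: str = ""
    observation_start_month: int = 1
    observation_end_month: int = 1
    has_epilepsy: bool = False


@dataclass
class SeizureHistory:
    """Per-patient SF series, keyed seizure_type -> month-of-life -> score.

    ``series[OVERALL]`` is the any-seizure-type series; additional keys are
    HPO CURIEs (e.g. ``HP:0012469`` for infantile spasms).
    """

    patient_id: str
    series: dict[str, dict[int, int]] = field(default_factory=dict)

    def sf(self, month: int, seizure_type: str = OVERALL, default: int = 0) -> int:
        return self.series.get(seizure_type, {}).get(month, default)

    def months(self, seizure_type: str = OVERALL) -> list[int]:
        return sorted(self.series.get(seizure_type, {}))

    def overall_vector(self, start: int, end: int, default: int = 0) -> list[int]:
        """Overall SF over the closed month interval [start, end]."""
        s = self.series.get(OVERALL, {})
        return [s.get(m, default) for m in range(start, end + 1)]


@dataclass(frozen=True)
class AsmExposure:
    """One anti-seizure-medication exposure interval, closed in months of life."""

    patient_id: str
    drug: str
    start_month: int
    end_month: int

    def covers(self, month: int) -> bool:
        return self.start_month <= month <= self.end_month


@dataclass(frozen=True)
class MilestoneRecord:
    patient_id: str
    milestone: str
    achieved: bool
    age_achieved_months: float | None
    age_last_assessed_months: float


@dataclass(frozen=True)
class AssessmentRecord:
    patient_id: str
    scale: str
    age_months: float
    value: float | str  # numeric score, or level "I".."V" for classification scales


@dataclass
class Cohort:
    patients: dict[str, Patient] = field(default_factory=dict)
    histories: dict[str, SeizureHistory] = field(default_factory=dict)
    exposures: list[AsmExposure] = field(default_factory=list)
    milestones: list[MilestoneRecord] = field(default_factory=list)
    assessments: list[AssessmentRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    #: (patient_id, seizure_type, month) triples whose SF was imputed.
    imputed: set = field(default_factory=set)

    # -- convenience views ------------------------------------------------
    def history(self, patient_id: str) -> SeizureHistory:
        return self.histories.setdefault(patient_id, SeizureHistory(patient_id))

    def exposures_for(self, patient_id: str) -> list[AsmExposure]:
        return [e for e in self.exposures if e.patient_id == patient_id]

    def drugs_active(self, patient_id: str, month: int) -> set[str]:
        return {e.drug for e in self.exposures
                if e.patient_id == patient_id and e.covers(month)}

    def sf_frame(self, seizure_type: str = OVERALL) -> pd.DataFrame:
        """Patients x months matrix of SF scores.

        Months outside a patient's observation window are NaN; months inside
        the window without a recorded score are 0 (no seizures documented).
        """
        if not self.patients:
            return pd.DataFrame()
        max_month = max(p.observation_end_month for p in self.patients.values())
        rows = {}
        for pid, pat in self.patients.items():
            h = self.histories.get(pid, SeizureHistory(pid))
            row = [float("nan")] * max_month
            for m in range(pat.observation_start_month, pat.observation_end_month + 1):
                row[m - 1] = h.sf(m, seizure_type)
            rows[pid] = row
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=range(1, max_month + 1)
        ).sort_index()


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(cohort: Cohort, *, require_imputed: bool = False) -> None:
    """Check structural invariants; raise :class:`CohortValidationError`.

    All violations are aggregated before raising so callers see every
    problem at once.
    """
    errors: list[str] = []
    for pid, pat in cohort.patients.items():
        if pid != pat.patient_id:
            errors.append(f"patient key {pid!r} != record id {pat.patient_id!r}")
        if pat.observation_start_month < 1:
            errors.append(f"{pid}: observation_start_month < 1")
        if pat.observation_end_month < pat.observation_start_month:
            errors.append(f"{pid}: empty observation window")
        if pat.sex not in VALID_SEXES:
            errors.append(f"{pid}: invalid sex {pat.sex!r}")
        if pat.variant_class not in VALID_VARIANT_CLASSES:
            errors.append(f"{pid}: invalid variant_class {pat.variant_class!r}")

    for pid, hist in cohort.histories.items():
        if pid not in cohort.patients:
            errors.append(f"history references unknown patient {pid!r}")
            continue
        pat = cohort.patients[pid]
        for stype, series in hist.series.items():
            for month, sf in series.items():
                if not (pat.observation_start_month <= month <= pat.observation_end_month):
                    errors.append(
                        f"{pid}/{stype}: month {month} outside observation window "
                        f"[{pat.observation_start_month}, {pat.observation_end_month}]")
                if sf == UNKNOWN_PRESENT:
                    if require_imputed:
                        errors.append(f"{pid}/{stype}: UNKNOWN_PRESENT at month "
                                      f"{month} in an imputed cohort")
                elif not (0 <= sf <= 5):
                    errors.append(f"{pid}/{stype}: SF {sf} out of range at month {month}")
        # overall must dominate per-type scores once everything is known
        overall = hist.series.get(OVERALL, {})
        for stype, series in hist.series.items():
            if stype == OVERALL:
                continue
            for month, sf in series.items():
                osf = overall.get(month, 0)
                if sf != UNKNOWN_PRESENT and osf != UNKNOWN_PRESENT and osf < sf:
                    errors.append(
                        f"{pid}: overall SF {osf} < {stype} SF {sf} at month {month}")

    for exp in cohort.exposures:
        if exp.patient_id not in cohort.patients:
            errors.append(f"exposure references unknown patient {exp.patient_id!r}")
            continue
        pat = cohort.patients[exp.patient_id]
        if exp.start_month > exp.end_month:
            errors.append(f"{exp.patient_id}/{exp.drug}: start_month > end_month")
        if (exp.start_month < pat.observation_start_month
                or exp.end_month > pat.observation_end_month):
            errors.append(f"{exp.patient_id}/{exp.drug}: exposure outside "
                          "observation window")

    for rec in cohort.milestones:
        if rec.patient_id not in cohort.patients:
            errors.append(f"milestone references unknown patient {rec.patient_id!r}")
        if rec.achieved:
            if rec.age_achieved_months is None:
                errors.append(f"{rec.patient_id}/{rec.milestone}: achieved without age")
            elif rec.age_achieved_months > rec.age_last_assessed_months:
                errors.append(f"{rec.patient_id}/{rec.milestone}: age_achieved > "
                              "age_last_assessed")
        elif rec.age_achieved_months is not None:
            errors.append(f"{rec.patient_id}/{rec.milestone}: not achieved but has "
                          "age_achieved")

    for rec in cohort.assessments:
        if rec.patient_id not in cohort.patients:
            errors.append(f"assessment references unknown patient {rec.patient_id!r}")

    if errors:
        raise CohortValidationError(errors)


# ---------------------------------------------------------------------------
# Median imputation of present-but-unknown months
# ---------------------------------------------------------------------------

def impute_unknown_present(cohort: Cohort, *, donors: str = "nonzero") -> Cohort:
    """Replace UNKNOWN_PRESENT cells with the cohort median SF of that month.

    For a month containing a present-but-unknown score the donor pool is, by
    default, patients with a *nonzero* known SF in that month (the target is
    known to be seizing, so seizure-free patients are uninformative donors);
    ``donors="all"`` uses every known score instead. Even-count medians are
    rounded half-up to stay on the ordinal grid. Months with no donors fall
    back to the global median of nonzero SF across all months (logged).

    Returns a new cohort; imputed cells are recorded in ``cohort.imputed``
    so downstream analyses can exclude them on request.
    """
    if donors not in ("nonzero", "all"):
        raise ValueError(f"donors must be 'nonzero' or 'all', got {donors!r}")

    out = copy.deepcopy(cohort)
    # donor pools are computed per (seizure_type, month) from the overall data
    pools: dict[tuple[str, int], list[int]] = {}
    global_pool: list[int] = []
    for hist in cohort.histories.values():
        for stype, series in hist.series.items():
            for month, sf in series.items():
                if sf == UNKNOWN_PRESENT:
                    continue
                if sf > 0:
                    global_pool.append(sf)
                if sf > 0 or donors == "all":
                    pools.setdefault((stype, month), []).append(sf)

    def _median(values: list[int]) -> int:
        values = sorted(values)
        n = len(values)
        mid = n // 2
        med = values[mid] if n % 2 else (values[mid - 1] + values[mid]) / 2
        return _round_half_up(med)

    n_imputed = 0
    for hist in out.histories.values():
        for stype, series in hist.series.items():
            for month, sf in list(series.items()):
                if sf != UNKNOWN_PRESENT:
                    continue
                pool = pools.get((stype, month), [])
                if pool:
                    value = _median(pool)
                elif global_pool:
                    value = _median(global_pool)
                    logger.warning(
                        "no donors for %s month %d; falling back to global "
                        "median of nonzero SF", stype, month)
                else:
                    raise CohortValidationError(
                        [f"cannot impute {hist.patient_id}/{stype} month {month}: "
                         "no patient has a known nonzero SF anywhere"])
                series[month] = value
                out.imputed.add((hist.patient_id, stype, month))
                n_imputed += 1
        # restore overall >= per-type dominance on imputed cells
        overall = hist.series.get(OVERALL, {})
        for stype, series in hist.series.items():
            if stype == OVERALL:
                continue
            for month, sf in series.items():
                if overall.get(month, 0) < sf:
                    overall[month] = sf
                    hist.series[OVERALL] = overall
    if n_imputed:
        logger.info("imputed %d present-but-unknown cells", n_imputed)
    return out


# ---------------------------------------------------------------------------
# I/O — long-format CSV files
# ---------------------------------------------------------------------------

_PATIENT_COLS = ["patient_id", "sex", "variant_class", "variant_label",
                 "obs_start_month", "obs_end_month", "has_epilepsy"]
_SEIZURE_COLS = ["patient_id", "seizure_type", "month", "sf"]
_ASM_COLS = ["patient_id", "drug", "start_month", "end_month"]
_MILESTONE_COLS = ["patient_id", "milestone", "achieved",
                   "age_achieved_months", "age_last_assessed_months"]
_ASSESSMENT_COLS = ["patient_id", "scale", "age_months", "value"]


def _require_columns(df: pd.DataFrame, cols: list[str], name: str,
                     errors: list[str]) -> bool:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        errors.append(f"{name}: missing required column(s) {missing}")
        return False
    return True


def read_cohort(directory: str | Path, *, validate_result: bool = True) -> Cohort:
    """Load a cohort from a directory of long-format CSV files.

    Expects ``patients.csv`` and ``seizures.csv``; ``asm.csv``,
    ``milestones.csv``, ``assessments.csv`` and ``provenance.json`` are
    optional. Validation errors are aggregated with file/row context.
    """
    directory = Path(directory)
    errors: list[str] = []
    cohort = Cohort(provenance={"source": str(directory)})

    ppath = directory / "patients.csv"
    if not ppath.exists():
        raise CohortValidationError([f"missing required file {ppath}"])
    pdf = pd.read_csv(ppath, dtype={"patient_id": str})
    if _require_columns(pdf, _PATIENT_COLS, "patients.csv", errors):
        for idx, row in pdf.iterrows():
            pid = str(row.patient_id)
            if pid in cohort.patients:
                errors.append(f"patients.csv row {idx + 2}: duplicate patient_id {pid!r}")
                continue
            cohort.patients[pid] = Patient(
                patient_id=pid,
                sex=str(row.sex),
                variant_class=str(row.variant_class),
                variant_label="" if pd.isna(row.variant_label) else str(row.variant_label),
                observation_start_month=int(row.obs_start_month),
                observation_end_month=int(row.obs_end_month),
                has_epilepsy=bool(row.has_epilepsy),
            )

    spath = directory / "seizures.csv"
    if not spath.exists():
        raise CohortValidationError(errors + [f"missing required file {spath}"])
    sdf = pd.read_csv(spath, dtype={"patient_id": str, "sf": str})
    if _require_columns(sdf, _SEIZURE_COLS, "seizures.csv", errors):
        seen: set[tuple[str, str, int]] = set()
        for idx, row in sdf.iterrows():
            pid, stype, month = str(row.patient_id), str(row.seizure_type), int(row.month)
            key = (pid, stype, month)
            if key in seen:
                errors.append(f"seizures.csv row {idx + 2}: duplicate "
                              f"(patient_id, seizure_type, month) = {key}")
                continue
            seen.add(key)
            token = str(row.sf).strip()
            if token == UNKNOWN_PRESENT_TOKEN:
                sf = UNKNOWN_PRESENT
            else:
                try:
                    sf = int(token)
                except ValueError:
                    errors.append(f"seizures.csv row {idx + 2}: bad sf value {token!r}")
                    continue
                if not (0 <= sf <= 5):
                    errors.append(f"seizures.csv row {idx + 2}: sf {sf} out of range")
                    continue
            cohort.history(pid).series.setdefault(stype, {})[month] = sf

    apath = directory / "asm.csv"
    if apath.exists():
        adf = pd.read_csv(apath, dtype={"patient_id": str})
        if _require_columns(adf, _ASM_COLS, "asm.csv", errors):
            cohort.exposures = _merge_overlaps([
                AsmExposure(str(r.patient_id), str(r.drug).lower(),
                            int(r.start_month), int(r.end_month))
                for r in adf.itertuples()])

    mpath = directory / "milestones.csv"
    if mpath.exists():
        mdf = pd.read_csv(mpath, dtype={"patient_id": str})
        if _require_columns(mdf, _MILESTONE_COLS, "milestones.csv", errors):
            for r in mdf.itertuples():
                age = None if pd.isna(r.age_achieved_months) else float(r.age_achieved_months)
                cohort.milestones.append(MilestoneRecord(
                    str(r.patient_id), str(r.milestone), bool(r.achieved),
                    age, float(r.age_last_assessed_months)))

    xpath = directory / "assessments.csv"
    if xpath.exists():
        xdf = pd.read_csv(xpath, dtype={"patient_id": str, "value": str})
        if _require_columns(xdf, _ASSESSMENT_COLS, "assessments.csv", errors):
            for r in xdf.itertuples():
                raw = str(r.value)
                try:
                    value: float | str = float(raw)
                except ValueError:
                    value = raw
                cohort.assessments.append(AssessmentRecord(
                    str(r.patient_id), str(r.scale), float(r.age_months), value))

    jpath = directory / "provenance.json"
    if jpath.exists():
        cohort.provenance = json.loads(jpath.read_text())

    if errors:
        raise CohortValidationError(errors)
    if validate_result:
        validate(cohort)
    return cohort


def _merge_overlaps(exposures: Iterable[AsmExposure]) -> list[AsmExposure]:
    """Merge overlapping/adjacent intervals per (patient, drug)."""
    by_key: dict[tuple[str, str], list[AsmExposure]] = {}
    for e in exposures:
        by_key.setdefault((e.patient_id, e.drug), []).append(e)
    merged: list[AsmExposure] = []
    for (pid, drug), items in sorted(by_key.items()):
        items.sort(key=lambda e: (e.start_month, e.end_month))
        cur_start, cur_end = items[0].start_month, items[0].end_month
        for e in items[1:]:
            if e.start_month <= cur_end + 1:
                cur_end = max(cur_end, e.end_month)
            else:
                merged.append(AsmExposure(pid, drug, cur_start, cur_end))
                cur_start, cur_end = e.start_month, e.end_month
        merged.append(AsmExposure(pid, drug, cur_start, cur_end))
    return merged


def canonical_frames(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Sorted long-format DataFrames; the canonical form for round-trips."""
    patients = pd.DataFrame(
        [{"patient_id": p.patient_id, "sex": p.sex,
          "variant_class": p.variant_class, "variant_label": p.variant_label,
          "obs_start_month": p.observation_start_month,
          "obs_end_month": p.observation_end_month,
          "has_epilepsy": p.has_epilepsy}
         for p in cohort.patients.values()],
        columns=_PATIENT_COLS).sort_values("patient_id").reset_index(drop=True)

    seiz_rows = []
    for hist in cohort.histories.values():
        for stype, series in hist.series.items():
            for month, sf in series.items():
                seiz_rows.append({
                    "patient_id": hist.patient_id, "seizure_type": stype,
                    "month": month,
                    "sf": UNKNOWN_PRESENT_TOKEN if sf == UNKNOWN_PRESENT else str(sf)})
    seizures = pd.DataFrame(seiz_rows, columns=_SEIZURE_COLS).sort_values(
        ["patient_id", "seizure_type", "month"]).reset_index(drop=True)

    asm = pd.DataFrame(
        [{"patient_id": e.patient_id, "drug": e.drug,
          "start_month": e.start_month, "end_month": e.end_month}
         for e in cohort.exposures],
        columns=_ASM_COLS).sort_values(_ASM_COLS).reset_index(drop=True)

    milestones = pd.DataFrame(
        [{"patient_id": m.patient_id, "milestone": m.milestone,
          "achieved": m.achieved, "age_achieved_months": m.age_achieved_months,
          "age_last_assessed_months": m.age_last_assessed_months}
         for m in cohort.milestones],
        columns=_MILESTONE_COLS).sort_values(
            ["patient_id", "milestone"]).reset_index(drop=True)

    assessments = pd.DataFrame(
        [{"patient_id": a.patient_id, "scale": a.scale,
          "age_months": a.age_months, "value": str(a.value)}
         for a in cohort.assessments],
        columns=_ASSESSMENT_COLS).sort_values(
            ["patient_id", "scale", "age_months"]).reset_index(drop=True)

    return {"patients": patients, "seizures": seizures, "asm": asm,
            "milestones": milestones, "assessments": assessments}


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write a cohort back to long-format CSV files (plus provenance.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = canonical_frames(cohort)
    frames["patients"].to_csv(directory / "patients.csv", index=False)
    frames["seizures"].to_csv(directory / "seizures.csv", index=False)
    if len(frames["asm"]):
        frames["asm"].to_csv(directory / "asm.csv", index=False)
    if len(frames["milestones"]):
        frames["milestones"].to_csv(directory / "milestones.csv", index=False)
    if len(frames["assessments"]):
        frames["assessments"].to_csv(directory / "assessments.csv", index=False)
    if cohort.provenance:
        (directory / "provenance.json").write_text(
            json.dumps(cohort.provenance, indent=2, sort_keys=True))
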