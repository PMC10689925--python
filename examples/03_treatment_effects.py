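"""Patient-month comparative effectiveness and time-locked response.

Classifies every evaluable patient-month (reduced / unchanged-or-worse /
freedom-maintained), builds exposed-vs-unexposed odds ratios per drug, and
aligns patients at first ASM initiation to show the response curve.
"""

from epinhs.asm_effectiveness import (comparative_effectiveness,
                                      month_response_table,
                                      time_locked_response)
from epinhs.synthetic_cohort import HP_SPASMS, GeneratorConfig, generate_cohort

cohort, _ = generate_cohort(GeneratorConfig(n_patients=300, seed=1))
months = month_response_table(cohort)
print(f"{len(months)} evaluable patient-months")

for drug, outcome in (("phenobarbital", "short_term"),
                      ("clobazam", "freedom_only"),
                      ("levetiracetam", "short_term")):
    est = comparative_effectiveness(cohort, drug, outcome, months=months)
    if est:
        print(f"{drug:14s} {outcome:12s} OR {est.or_point:4.2f} "
              f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f}, "
              f"n={est.n_patients} patients)")

curve = time_locked_response(cohort, None, horizon=6, spasm_type=HP_SPASMS)
row5 = curve.set_index("months_since_initiation").loc[5]
row3 = curve.set_index("months_since_initiation").loc[3]
print(f"seizure burden reduction 5 months after any-ASM initiation: "
      f"{100 * row5['reduction']:.0f}%")
print(f"spasm offset within 3 months of initiation: "
      f"{100 * row3['spasm_offset_fraction']:.0f}%")

# OR > 1 with CI excluding 1 recovers the injected drug effect; the
# time-locked curve shows burden roughly halving within ~5 months.
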