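"""Derive and verify vBMD screening thresholds on synthetic cohorts.

Generates the experimental-preset cohort (105 subjects, three DXA-
defined groups), derives Youden-optimal vBMD thresholds per vertebra
and for the L1-L4 average, then scores an independent test-preset
cohort (75 subjects) at those fixed thresholds — the same two-stage
design used to evaluate opportunistic screening clinically.
"""

from tcmbmd import default_params, generate_cohort, pearson_r, performance_table
from tcmbmd.cohort import VERTEBRAE, youden_threshold, roc_curve, endpoint_labels, subject_scores

experimental = generate_cohort(default_params("experimental"), seed=11)
test = generate_cohort(default_params("test"), seed=12)

# the reference standard is the DXA-style label derived from T-scores
experimental = experimental.assign(group=experimental["tscore_group"])
test = test.assign(group=test["tscore_group"])

for v in VERTEBRAE:
    r, p = pearson_r(experimental[f"vbmd_{v}"], experimental[f"abmd_{v}"])
    print(f"{v}: Pearson r(vBMD, aBMD) = {r:.3f} (p = {p:.2g})")

print("\nExperimental cohort, Youden-optimal thresholds (osteoporosis):")
perf = performance_table(experimental, "osteoporosis")
print(perf.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

thresholds = dict(zip(perf["vertebra"], perf["threshold"]))
print("\nTest cohort scored at the fixed experimental thresholds:")
print(
    performance_table(test, "osteoporosis", thresholds=thresholds).to_string(
        index=False, float_format=lambda x: f"{x:.3f}"
    )
)
print(
    "\nSensitivity/specificity/accuracy are percentages; 'average' uses the "
    "per-subject mean vBMD of L1-L4 as the predictor.  A subject tests "
    "positive when vBMD <= threshold (low density indicates disease)."
)
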