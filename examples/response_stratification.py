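"""Treatment-response stratification of the day-3 signature score change.

Simulates a paired baseline/day-3 trial arm (grade counts 10/6/11/16/8/11
across NR..ACR100) in which better responders lose a larger fraction of the
planted pathway effect by day 3, then stratifies the per-patient score change
by response grade.
"""

from sigscore import (
    ResponseCohortConfig,
    generate_response_cohort,
    paired_change,
    signature_score,
    stratify_by_response,
)

matrix, response, truth = generate_response_cohort(ResponseCohortConfig(seed=5))
annotations = truth.extra["annotations"]
controls = annotations.index[annotations["group"] == "control"]

scores = signature_score(matrix, list(controls), list(truth.signature_genes))
deltas = paired_change(scores, response)
result = stratify_by_response(deltas)

print(result.summary.round(2).to_string())
print(f"\nKruskal-Wallis H={result.statistic:.1f}  p={result.pvalue:.3g}")
print(f"monotone trend NR -> ACR100: {result.monotone_trend}")
print(
    "\nMedian score change should fall from ~0 in non-responders towards "
    "-(score shift) in complete responders, and the omnibus test rejects."
)
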