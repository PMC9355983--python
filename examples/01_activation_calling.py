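"""Call NOTCH pathway activation on a simulated tumor cohort.

Simulates 10 NOTCH-activated and 10 wild-type samples (signature up-set
genes 4-fold elevated, down-set suppressed to 0.25x in activated tumors),
normalizes the counts, scores every sample with ssGSEA and kTSP, and emits
binary activation calls.
"""

from notchcall import (
    CohortSpec,
    call_activation,
    default_signature,
    score_cohort,
    simulate_expression_cohort,
)
from notchcall.de import normalize_counts, size_factors

signature = default_signature()
spec = CohortSpec(
    n_activated=10, n_wildtype=10, n_genes=1000,
    up_effect=4.0, down_effect=0.25, dispersion=0.1, seed=1,
)
matrix, metadata, truth = simulate_expression_cohort(spec, signature)

norm = normalize_counts(matrix, size_factors(matrix))
calls = call_activation(score_cohort(norm, signature))

print(calls.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
accuracy = (
    calls.set_index("sample_id")["call"]
    .map({"activated": "activated", "not_activated": "wild_type"})
    .loc[truth.index]
    .eq(truth)
    .mean()
)
print(f"\nlabel recovery vs simulation truth: {accuracy:.0%}")
print(
    "ssgsea_score is the cohort-rescaled running-sum enrichment of the 21-gene "
    "up-set;\nktsp_score is the fraction of (down, up) gene pairs ordered "
    "down < up;\na sample is 'activated' when both scores clear their thresholds."
)
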