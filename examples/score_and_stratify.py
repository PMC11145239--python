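"""Concordance scoring and cutoff-optimized survival stratification.

Each sample gets +1 per signature gene expressed on the signature's side of
the per-gene cohort median. A score cutoff then splits the cohort into
Expected High / Moderate Vascularity groups; the cutoff is chosen to
minimize the two-group log-rank p-value, and a permutation calibration
reports how much of that significance is selection optimism.
"""

from vascsig import PipelineConfig, run_all

cfg = PipelineConfig(simulate={}, seed=7, n_permutations=200)
bundle = run_all(cfg)
summary = bundle["summary"]

print(f"signature size: {summary['signature_size']}")
print(f"chosen score cutoff: {summary['score_cutoff']}")
print(f"group sizes (high/low score): {summary['expected_group_sizes']}")
print(f"log-rank p at best cutoff: {summary['logrank_p']:.4f}")
print(f"permutation-adjusted p:    {summary['permutation_adjusted_p']:.4f}")
print(f"median survival (days): {summary['median_survival_days']}")
# The adjusted p is never smaller than the naive minimum: scanning every
# cutoff for the best split inflates significance, and the permutation
# null quantifies by how much.
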