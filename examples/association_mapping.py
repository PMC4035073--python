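"""Mixed-model GWAS with permutation P-values, skew intersection and
candidate-gene lookup — the full pipeline on one synthetic study.

Per trait: EMMAX-style MLM scan over markers in skewed regions, family-wise
permutation P-values (max-F over 500 phenotype permutations), intersection
with the ancestry scan's skew calls, and a 4-Mb candidate-feature search
around each surviving SNP.
"""

from introscan import SimulationConfig, generate_fixture, run_pipeline, score_against_truth

bundle = generate_fixture(SimulationConfig(seed=7))
result = run_pipeline(
    bundle.geno,
    bundle.panel,
    bundle.phenotypes,
    features=bundle.features,
    n_perm=500,
    seed=7,
)

for trait, hits in result.hits.items():
    print(f"\n{trait}: {len(hits)} significant skewed marker(s)")
    cols = ["marker_id", "chromosome", "position_bp", "neglog10_p", "perm_p", "skew_class"]
    print(hits[cols].round(3).to_string(index=False))
    cand = result.candidates[trait]
    named = cand[["marker_id", "feature_id", "feature_kind", "distance_bp"]]
    print("candidates within 4 Mb:")
    print(named.to_string(index=False))
    print("allele effects (trait mean +- sd per homozygote class):")
    print(result.allele_effects[trait].round(2).to_string(index=False))

print("\nscore against ground truth:")
for k, v in score_against_truth(result, bundle.truth).items():
    print(f"  {k}: {v}")
# A planted QTL is recovered when its marker is significant (permutation
# P < 0.01), lies in a skewed window, and the planted gene appears among the
# candidates at distance ~0.
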