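"""Generate a synthetic rice breeding study with known ground truth.

Builds two diverged homozygous parental pools (overseas indica, domestic
japonica), 60 admixed high-yielding (HY) mosaic lines with three regions
selected toward 0.9 indica frequency, and QTL-driven traits, then writes the
bundle to ./study_fixture/ in plain-text formats.
"""

from introscan import SimulationConfig, generate_fixture

config = SimulationConfig(seed=7)
bundle = generate_fixture(config, out_dir="study_fixture", force=True)

g = bundle.geno
print(f"genotypes: {g.n_cultivars} cultivars x {g.n_markers} markers")
print(f"groups: { {k.value: v for k, v in bundle.panel.sizes().items()} }")
print(f"traits: {bundle.phenotypes.traits}")
print("planted skew regions:")
for r in bundle.truth.skew_regions:
    print(f"  {r.chromosome}:{r.start_bp}-{r.end_bp} -> indica freq {r.target_indica_freq}")
print("planted QTLs:")
print(bundle.truth.qtls.to_string(index=False))
# The truth table records where introgression and causal loci were planted,
# so every later analysis stage can be scored against it.
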