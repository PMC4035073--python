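"""Choose a genotyping panel size from the mean complete-LD curve.

For random marker subsets of growing size, adjacent-pair delta-squared is
averaged over pairs strictly inside (0, 1).  The curve rises while extra
markers still land in new haplotype blocks and plateaus once marker spacing
is small relative to the LD decay length — the plateau marks a practical
panel size.
"""

from introscan import (
    Group,
    SimulationConfig,
    filter_core_informative,
    generate_fixture,
    ld_subset_curve,
    select_panel,
)

config = SimulationConfig(
    n_markers=2400, block_length_mean_bp=3_000_000, seed=7, skew_regions=[], qtls=[]
)
bundle = generate_fixture(config)
hy = bundle.panel.members(Group.HY)

core = filter_core_informative(bundle.geno, bundle.panel.members(Group.PD))
print(f"core-informative markers (no missing, minor allele in >=3 of 14): {len(core)}")

sizes = [150, 300, 600, 900, 1200, 1800, 2400]
points, summary = ld_subset_curve(bundle.geno, hy, sizes, reps=10, seed=7)
print(summary.round(4).to_string(index=False))

panel = select_panel(list(bundle.geno.markers.marker_ids), 1152, seed=7, geno=bundle.geno)
print(f"working panel: {len(panel)} markers selected uniformly at random")
# Read the table bottom-up: once the mean stops growing, denser panels no
# longer add linkage information for this population.
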