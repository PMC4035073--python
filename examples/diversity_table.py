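"""Per-population marker diversity: MAF, gene diversity (He) and PIC.

Means are reported raw and sample-size adjusted by averaging over 10 random
subsets of 14 cultivars, so populations of different sizes are comparable.
"""

from introscan import SimulationConfig, diversity_table, generate_fixture

bundle = generate_fixture(SimulationConfig(seed=7))
table = diversity_table(bundle.geno, bundle.panel, adjust_n=14, reps=10, seed=7)
print(table.round(3).to_string(index=False))
# HY lines mix two diverged pools, so their He/PIC exceed either parental
# pool's; the adjusted columns remove the effect of unequal sample size.
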