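"""Per-taxon functional contributions to the nitrogen pathways.

The contribution of a taxon to a pathway is the proportion of reaction steps
it is involved in (carrying at least one gene of the step, or -- in
``full_step`` mode -- satisfying the step alone).
"""

from nitrocycle import (
    contribution_matrix,
    contribution_wide,
    default_registry,
    derive_presence,
    select_core_taxa,
    simulate_observed_pattern,
)

registry = default_registry()
table = simulate_observed_pattern(registry)
presence = derive_presence(table)
core = select_core_taxa(table)

results = contribution_matrix(registry, presence, core, layers=["DNA"], stages=["adult"])
wide = contribution_wide(results, "DNA", "adult")
print(wide.round(2).to_string())

# Each cell is the involved-step proportion of that order in that pathway on
# the adult metagenome layer; Enterobacterales carries essentially every EAA
# pathway (argF excepted), while orders contributing only nifH show 0.5 on
# the two-step nitrogen-fixation pathway.
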