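"""Detect a tandem iteron array in a synthetic plasmid's oriV region.

Builds a 5-kb circular plasmid carrying a rep gene with four 22-bp iterons
planted upstream (one substitution allowed per copy), then recovers the
array from the 500-bp window 5' of the rep start codon.
"""

from plasmidnet import (
    IteronSpec,
    RepModuleSpec,
    find_iteron_arrays_both_strands,
    generate_plasmid,
    upstream_window,
)

record, truth = generate_plasmid(
    5000,
    gc=0.38,
    rep=RepModuleSpec(iterons=IteronSpec(unit_length=22, copies=4, substitution_prob=0.03)),
    seed=11,
    plasmid_id="demo",
)
planted = truth.planted_iterons[0]
print(f"planted: {planted.copy_count} x {planted.unit_length} bp at {planted.copy_starts}")

rep_gene = record.features[0]
window = upstream_window(record, rep_gene, 500)
for arr in find_iteron_arrays_both_strands(window, plasmid_id=record.id):
    print(
        f"found:   {arr.copy_count} x {arr.unit_length} bp on '{arr.strand}', "
        f"consensus {arr.consensus.render()} "
        f"(mean mismatch {arr.mean_mismatch_frac:.3f})"
    )

# The consensus is printed in degenerate (X/Y) notation: an invariant column
# shows its base, a variable column lists the observed bases, majority first.
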