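"""Screen an origin-wrapping REP module for restriction-site availability.

A module whose span crosses the circular plasmid's origin (start > end) is
extracted as one forward-running fragment and scanned against the 13
multiple-cloning-site six-cutters; every enzyme that does NOT cut remains
usable in a vector built around this module.
"""

from plasmidnet import MCS_ENZYMES, ModuleRegion, RepModuleSpec, generate_plasmid, screen_module

record, truth = generate_plasmid(
    3124, gc=0.37, rep=RepModuleSpec(site_free=True), seed=4, plasmid_id="demo"
)

# same span geometry as a replicon whose REP module wraps the origin
region = ModuleRegion("demo", 2670, 2399, "REP")
result = screen_module(record, region, MCS_ENZYMES)

frag_len = (record.length - region.start + 1) + region.end
print(f"module spans {region.start}..{region.end} (wraps origin): {frag_len} bp")
print(f"available (non-cutting): {result.available}/13 -> {', '.join(result.non_cutting)}")
for name, positions in sorted(result.cutting.items()):
    print(f"cutting: {name} at fragment position(s) {positions}")

# Positions are 1-based on the extracted fragment, 5'->3' from the region
# start; a high available count marks the module as a good vector backbone.
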