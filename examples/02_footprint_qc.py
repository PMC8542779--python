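"""Footprint-level QC: length distribution, P-site region occupancy.

Simulates one Ribo-seq library's footprints, assigns them back to genes by
P-site, and prints the QC summaries a ribosome-profiling analyst inspects
first.
"""

import pandas as pd

from ribojoint import (
    SimulationConfig,
    assign_footprints,
    generate_annotation,
    length_histogram,
    region_ratios,
    simulate_footprints,
)

config = SimulationConfig(seed=3)
annotation = generate_annotation(200, seed=3)
counts = pd.DataFrame(
    {"M_ribo_1": [150] * 200},
    index=pd.Index([m.gene_id for m in annotation], name="gene_id"),
)
footprints = simulate_footprints(counts, annotation, config, "M_ribo_1")

freq, mode = length_histogram(footprints)
print(f"{len(footprints)} footprints; length frequencies:")
print((freq * 100).round(2).to_string())
print(f"modal footprint length: {mode} nt (healthy libraries peak near 31 nt)")

assigned, tally = assign_footprints(footprints, annotation)
ratios = region_ratios(tally)
print()
print("P-site region occupancy (% of assigned footprints):")
for region in ("utr5", "cds", "utr3"):
    print(f"  {region:>5}: {ratios[region]:6.2f}%")
print(
    "\nCDS should dominate: ribosomes sit on coding sequence. The per-gene\n"
    f"assigned counts sum to {assigned.sum()}, exactly the simulated total —\n"
    "footprint records conserve the count matrix."
)
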