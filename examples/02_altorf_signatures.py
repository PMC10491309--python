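"""altORF translation signatures: 3'UTR:ORF ratios and the stop-codon
metagene.

Ribosomes that re-initiate on 3' cleavage fragments leave footprints in
normally untranslated regions.  Two summaries make that visible: the
aggregate ratio of 3'UTR to CDS footprint rpm, and the average normalized
occupancy around the stop codon.
"""

import numpy as np

from riboclast import (
    SimulationConfig,
    assign_psites,
    count_regions,
    generate_experiment,
    metagene,
    to_rpm,
    utr_orf_ratio,
)

result = generate_experiment(SimulationConfig(
    n_genes=400, replicates_per_condition=2,
    footprint_depth=500_000, rnaseq_depth=200_000, rng_seed=11,
))
tx = result.transcriptome
tracksets = [assign_psites(result.footprints[s], tx, sample_id=s)
             for s in result.footprints]
rpm = to_rpm(count_regions(tracksets, tx))

ratios = utr_orf_ratio(rpm, which="utr3", scope="aggregate", min_cds_rpm=1.0)
print(ratios.to_string(index=False))

profiles = {}
for ts in tracksets:
    if ts.sample_id in ("control_rep1", "treated_rep1"):
        profiles[ts.sample_id] = metagene(ts, tx, anchor="stop_codon",
                                          window=(60, 90), min_cds_density=0.5)
for name, prof in profiles.items():
    downstream = prof.mean_over(9, 90)
    print(f"{name}: mean occupancy downstream of the stop = {downstream:.3f} "
          f"(CDS level = 1.0), genes = {prof.n_genes}")
# Treated samples show a ratio tens of times the control and clearly
# elevated occupancy past the stop codon — the altORF signature of
# fragment re-initiation.  Controls sit at the uniform background.
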