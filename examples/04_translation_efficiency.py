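"""Translation-efficiency changes: injection and recovery.

TE contrasts CDS footprint density with CDS RNA-seq density.  Here 40
strongly induced genes carry injected log2 TE shifts of +/-2; the
classifier should place them above/below the fold-change diagonal while
leaving unshifted genes on it.
"""

import numpy as np

from riboclast import (
    SimulationConfig,
    CleavageModel,
    assign_psites,
    classify_te_changes,
    count_regions,
    differential_expression,
    generate_experiment,
)

induced = tuple(f"g{i:04d}" for i in range(80))
shifts = {f"g{i:04d}": (2.0 if i < 20 else -2.0) for i in range(40)}
result = generate_experiment(SimulationConfig(
    n_genes=1000, replicates_per_condition=3,
    footprint_depth=1_000_000, rnaseq_depth=1_000_000,
    global_loss_fraction=0.0, induced_genes=induced, induction_factor=32.0,
    te_shift_genes=shifts, uorf_gene_fraction=0.0,
    cleavage=CleavageModel.rnasel_like(0.0), rng_seed=31,
))

tx = result.transcriptome
tracksets = [assign_psites(result.footprints[s], tx, sample_id=s)
             for s in result.footprints]
counts = count_regions(tracksets, tx)
de_ribo = differential_expression(counts["cds"], result.conditions,
                                  "control", "treated")
de_rna = differential_expression(result.rnaseq, result.conditions,
                                 "control", "treated")

classes = classify_te_changes(de_ribo, de_rna)  # gates: |lfc|>4, padj<0.01,
print(classes["category"].value_counts().to_string())  # base_mean>50, 2-fold TE

expected = {g: ("te_up" if s > 0 else "te_down") for g, s in shifts.items()}
hit = np.mean([classes.loc[g, "category"] == expected[g] for g in shifts])
mean_delta_up = classes.loc[[g for g, s in shifts.items() if s > 0],
                            "delta_log2_te"].mean()
print(f"injected genes recovered: {hit * 100:.0f}%")
print(f"mean delta_log2_te of +2-injected genes: {mean_delta_up:.2f}")
# Recovery near 100% with the estimated shift close to the injected +2:
# the ribo-vs-RNA fold-change difference reads TE changes off the diagonal.
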