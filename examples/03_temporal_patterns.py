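"""Classify DE genes into early/late up/down temporal patterns.

Runs differential expression on a synthetic time course, assigns
early/late phases from the sampling grid, and classifies every DE gene
as EU, ED, LU, LD or OTHER; the confusion against the planted truth is
printed.
"""

import pandas as pd

from xregen.de_analysis import DEConfig, run_de
from xregen.synthetic_data import GeneratorConfig, generate_timecourse_counts
from xregen.temporal import assign_phases, classify_all

cfg = GeneratorConfig(seed=0, n_genes_per_species=800)
matrices, truth = generate_timecourse_counts(cfg)

species = "planaria"
cm = matrices[species]
result = run_de(cm, DEConfig())

wide_fc = result.table.pivot(index="gene_id", columns="time_h", values="log2fc").sort_index()
wide_de = result.table.pivot(index="gene_id", columns="time_h", values="is_de").loc[wide_fc.index]
phases = assign_phases(cm.time_points_h, species=species)
print(f"phases for {species}: early={phases.early_indices} late={phases.late_indices}")

calls = classify_all(
    wide_fc.to_numpy(), wide_de.to_numpy(dtype=bool), list(wide_fc.index), phases
)
planted = pd.Series(truth.pattern_labels[species], name="planted")
merged = calls.set_index("gene_id").join(planted, how="inner")
print("\nplanted pattern vs called pattern:")
print(pd.crosstab(merged.planted, merged.pattern).to_string())
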