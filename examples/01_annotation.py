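"""Annotate one species' genes from an alignment hit table.

Generates a synthetic hit table, applies the permissive significance
filter and taxon allow-list, then derives each gene's human best match
and strict-cutoff hit list.
"""

from xregen.annotation import (
    DEFAULT_TAXON_ALLOW,
    GeneCluster,
    annotate_genes,
    annotation_table,
    filter_hits,
)
from xregen.synthetic_data import GeneratorConfig, generate_hit_tables, generate_reference_universe

cfg = GeneratorConfig(seed=0, n_genes_per_species=300, n_planted_ortholog_groups=40)
universe = generate_reference_universe(cfg)
tables, truth = generate_hit_tables(cfg, universe)

hits = tables["planaria"]
kept = filter_hits(hits, sig_threshold=1e-2, taxon_allow=DEFAULT_TAXON_ALLOW)
print(f"raw hits: {len(hits)}, after filtering: {len(kept)}")

gene_ids = sorted({h.query_id for h in kept})
clusters = [GeneCluster(g, frozenset([g]), g) for g in gene_ids]
annotations = annotate_genes(clusters, kept, list_sig_threshold=1e-15)

table = annotation_table(annotations)
n_best = (table.best_match_acc != "").sum()
n_list = (table.list_match != "").sum()
print(f"genes with a human best match: {n_best}/{len(table)}")
print(f"genes with a strict-cutoff hit list: {n_list}/{len(table)}")
print(table.head(5).to_string(index=False))
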