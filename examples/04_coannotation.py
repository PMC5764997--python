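"""Link genes across species through shared reference-database hits.

Best-match mode links genes carrying the same human best-match
accession and yields Venn-style intersection counts; list-match mode
links genes whose strict-cutoff hit lists overlap by more than 80% of
the smaller list.
"""

from xregen.annotation import DEFAULT_TAXON_ALLOW, GeneCluster, annotate_genes, filter_hits
from xregen.coannotation import coannotate_best, coannotate_list, venn_counts, venn_table
from xregen.synthetic_data import GeneratorConfig, generate_hit_tables, generate_reference_universe

cfg = GeneratorConfig(seed=0, n_genes_per_species=400, n_planted_ortholog_groups=60)
universe = generate_reference_universe(cfg)
tables, truth = generate_hit_tables(cfg, universe)

annotations = {}
for species, hits in tables.items():
    kept = filter_hits(hits, 1e-2, DEFAULT_TAXON_ALLOW)
    gene_ids = sorted({h.query_id for h in kept})
    clusters = [GeneCluster(g, frozenset([g]), g) for g in gene_ids]
    annotations[species] = annotate_genes(clusters, kept)

cmap = coannotate_best(annotations)
print("accessions per Venn region (best-match mode):")
print(venn_table(venn_counts(cmap)).to_string(index=False))

lmap = coannotate_list(
    annotations["hydra"], annotations["planaria"], species_a="hydra", species_b="planaria"
)
print(f"\nhydra-planaria list-match links: {len(lmap.pairs)}")
print(f"planted ortholog groups: {len(truth.ortholog_groups)}")
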