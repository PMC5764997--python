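"""Generator determinism, planted-truth consistency, reader compatibility."""

import numpy as np
import pytest

from xregen.annotation import DEFAULT_TAXON_ALLOW, annotate_genes, filter_hits, GeneCluster
from xregen.io_formats import read_counts, read_gene_list, read_hit_table
from xregen.synthetic_data import (
    GeneratorConfig,
    generate_hit_tables,
    generate_reference_universe,
    generate_signature_fixture,
    generate_timecourse_counts,
    write_fixture,
)

SMALL = dict(
    n_genes_per_species=80,
    n_planted_ortholog_groups=20,
    n_common_de=4,
    n_accessions=800,
    planted_patterns={p: (5, 3.0) for p in ("EU", "ED", "LU", "LD")},
)


class TestUniverse:
    def test_exact_proportions(self):
        cfg = GeneratorConfig(
            n_accessions=100,
            taxon_proportions={"human": 0.5, "mouse": 0.2, "other": 0.2, "bacteria": 0.1},
        )
        uni = generate_reference_universe(cfg)
        assert len(uni.by_species("human")) == 50
        assert len(uni.by_species("bacteria")) == 10
        assert all(uni.taxon[a] == "Bacteria" for a in uni.by_species("bacteria"))

    def test_same_seed_identical(self):
        u1 = generate_reference_universe(GeneratorConfig(seed=5, n_accessions=50))
        u2 = generate_reference_universe(GeneratorConfig(seed=5, n_accessions=50))
        assert u1.accessions == u2.accessions and u1.species == u2.species

    def test_zero_accessions_empty(self):
        uni = generate_reference_universe(GeneratorConfig(n_accessions=0))
        assert uni.accessions == []


class TestHitTables:
    def test_planted_groups_share_top_accession(self):
        cfg = GeneratorConfig(seed=1, decoy_hit_rate=0.0, bacterial_hit_rate=0.0, **SMALL)
        uni = generate_reference_universe(cfg)
        tables, truth = generate_hit_tables(cfg, uni)
        for gname, members in truth.ortholog_groups.items():
            acc = truth.group_accession[gname]
            for sp, gid in members.items():
                hits = [h for h in tables[sp] if h.query_id == gid]
                top = max(hits, key=lambda h: h.bit_score)
                assert top.subject_acc == acc

    def test_group_hit_lists_disjoint(self):
        cfg = GeneratorConfig(seed=2, decoy_hit_rate=0.0, **SMALL)
        uni = generate_reference_universe(cfg)
        _, truth = generate_hit_tables(cfg, uni)
        seen = set()
        for accs in truth.group_hit_list.values():
            assert not (set(accs) & seen)
            seen.update(accs)

    def test_bacterial_hits_removed_by_filter(self):
        cfg = GeneratorConfig(seed=3, bacterial_hit_rate=1.0, **SMALL)
        uni = generate_reference_universe(cfg)
        tables, _ = generate_hit_tables(cfg, uni)
        for recs in tables.values():
            assert any(h.subject_taxon == "Bacteria" for h in recs)
            kept = filter_hits(recs, 1e-2, DEFAULT_TAXON_ALLOW)
            assert all(h.subject_taxon != "Bacteria" for h in kept)

    def test_same_seed_identical_tables(self):
        cfg = GeneratorConfig(seed=4, **SMALL)
        uni = generate_reference_universe(cfg)
        t1, _ = generate_hit_tables(cfg, uni)
        t2, _ = generate_hit_tables(cfg, uni)
        assert t1 == t2

    def test_more_groups_than_genes_rejected(self):
        with pytest.raises(ValueError, match="ortholog groups"):
            GeneratorConfig(n_genes_per_species=5, n_planted_ortholog_groups=10)


class TestTimecourses:
    def test_planted_means_show_expected_log2fc(self):
        # noise-free expectation: average planted EU log2fc near +3 early
        cfg = GeneratorConfig(
            seed=5,
            n_genes_per_species=3000,
            n_planted_ortholog_groups=0,
            n_common_de=0,
            nb_dispersion=0.0,
            planted_patterns={"EU": (300, 3.0)},
        )
        mats, truth = generate_timecourse_counts(cfg)
        cm = mats["planaria"]
        planted = [i for i, g in enumerate(cm.gene_ids) if g in truth.pattern_labels["planaria"]]
        early_mean = cm.counts[planted, 1].mean()
        base_mean = cm.counts[planted, 0].mean()
        assert np.log2(early_mean / base_mean) == pytest.approx(3.0, abs=0.1)
        late_mean = cm.counts[planted, -1].mean()
        assert abs(np.log2(late_mean / base_mean)) < 0.1

    def test_same_seed_identical_counts(self):
        cfg = GeneratorConfig(seed=6, **SMALL)
        m1, _ = generate_timecourse_counts(cfg)
        m2, _ = generate_timecourse_counts(cfg)
        for sp in m1:
            np.testing.assert_array_equal(m1[sp].counts, m2[sp].counts)

    def test_zero_effect_pattern_rejected(self):
        with pytest.raises(ValueError, match="zero effect"):
            GeneratorConfig(planted_patterns={"EU": (5, 0.0)})

    def test_common_de_genes_are_ortholog_genes(self):
        cfg = GeneratorConfig(seed=7, **SMALL)
        uni = generate_reference_universe(cfg)
        _, truth = generate_hit_tables(cfg, uni)
        _, truth = generate_timecourse_counts(cfg, truth)
        assert len(truth.common_de_accessions) == cfg.n_common_de
        for sp, labels in truth.pattern_labels.items():
            for gname in sorted(truth.ortholog_groups)[: cfg.n_common_de]:
                assert truth.ortholog_groups[gname][sp] in labels


class TestSignatureFixture:
    def test_planted_overlap_truths(self):
        cfg = GeneratorConfig(seed=8, **SMALL)
        uni = generate_reference_universe(cfg)
        _, truth = generate_hit_tables(cfg, uni)
        lists, per_dataset, truth = generate_signature_fixture(cfg, uni, truth)
        from xregen.signatures import consensus_signature, shared_members

        assert shared_members(lists, k=3) == {a.upper() for a in truth.signature_shared_all}
        sig = consensus_signature(per_dataset, {"murine": 2, "human": 3})
        assert sig.members == set(truth.consensus_members)

    def test_same_seed_identical_lists(self):
        cfg = GeneratorConfig(seed=9, **SMALL)
        uni = generate_reference_universe(cfg)
        l1, d1, _ = generate_signature_fixture(cfg, uni)
        l2, d2, _ = generate_signature_fixture(cfg, uni)
        assert l1 == l2 and d1 == d2


class TestFixtureDirectory:
    def test_emitted_files_pass_readers(self, tmp_path):
        cfg = GeneratorConfig(seed=10, **SMALL)
        write_fixture(cfg, tmp_path)
        for sp in cfg.species:
            hits = read_hit_table(tmp_path / f"hits_{sp}.tsv")
            assert hits
            cm = read_counts(tmp_path / f"counts_{sp}.tsv", species=sp)
            assert cm.n_genes == cfg.n_genes_per_species
        for name in ("list_a", "list_b", "list_c"):
            assert read_gene_list(tmp_path / f"signature_{name}.txt")

    def test_rewrite_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(seed=11, **SMALL)
        write_fixture(cfg, tmp_path / "a")
        write_fixture(cfg, tmp_path / "b")
        for p in sorted((tmp_path / "a").iterdir()):
            assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes()


def test_noise_free_fixture_recovered_by_annotation():
    """Planted truth equals annotation output when no decoys exist."""
    cfg = GeneratorConfig(seed=12, decoy_hit_rate=0.0, bacterial_hit_rate=0.0, **SMALL)
    uni = generate_reference_universe(cfg)
    tables, truth = generate_hit_tables(cfg, uni)
    for sp, recs in tables.items():
        kept = filter_hits(recs, 1e-2, DEFAULT_TAXON_ALLOW)
        gene_ids = sorted({h.query_id for h in kept})
        clusters = [GeneCluster(g, frozenset([g]), g) for g in gene_ids]
        ann = annotate_genes(clusters, kept)
        for gname, members in truth.ortholog_groups.items():
            assert ann[members[sp]].best_match_acc == truth.group_accession[gname]
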