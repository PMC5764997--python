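"""Hit filtering, transcript clustering, best-match and list-match logic."""

import random

import pytest

from xregen.annotation import (
    GeneCluster,
    aggregate_gene_hits,
    annotate_genes,
    cluster_transcripts,
    filter_hits,
    human_best_match,
    list_match_annotation,
)
from xregen.io_formats import HitRecord


def hit(q="t1", acc="P1", taxon="Eukaryota", species="human", score=100.0, sig=1e-20, **kw):
    return HitRecord(q, acc, taxon, species, score, sig, **kw)


class TestFilterHits:
    def test_strict_sig_kept_loose_discarded(self):
        kept = filter_hits([hit(sig=1e-16), hit(acc="P2", sig=1e-14)], sig_threshold=1e-15)
        assert [h.subject_acc for h in kept] == ["P1"]

    def test_threshold_is_inclusive_keep(self):
        assert len(filter_hits([hit(sig=1e-15)], sig_threshold=1e-15)) == 1

    def test_bacterial_hit_discarded_regardless_of_sig(self):
        assert filter_hits([hit(taxon="Bacteria", sig=1e-100)], sig_threshold=1e-2) == []

    def test_empty_allow_list_is_config_error(self):
        with pytest.raises(ValueError, match="allow-list"):
            filter_hits([hit()], taxon_allow=[])

    def test_order_preserved(self):
        hits = [hit(q=f"t{i}", sig=1e-20) for i in range(5)]
        assert [h.query_id for h in filter_hits(hits)] == [f"t{i}" for i in range(5)]


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestClusterTranscripts:
    def test_identical_sequences_co_cluster(self):
        rng = random.Random(0)
        s = _random_seq(rng, 300)
        clusters = cluster_transcripts({"a": s, "b": s}, identity_threshold=0.8)
        assert len(clusters) == 1 and clusters[0].member_ids == {"a", "b"}

    def test_unrelated_sequences_stay_apart(self):
        rng = random.Random(1)
        clusters = cluster_transcripts(
            {"a": _random_seq(rng, 300), "b": _random_seq(rng, 300)}, identity_threshold=0.8
        )
        assert len(clusters) == 2

    def test_partition_matches_bruteforce_identity(self):
        # A == B identical, C unrelated: brute-force pairwise exact identity
        # (fraction of positions equal) confirms the partition {A,B},{C}
        rng = random.Random(2)
        a = _random_seq(rng, 240)
        c = _random_seq(rng, 240)

        def exact_identity(x, y):
            return sum(1 for u, v in zip(x, y) if u == v) / max(len(x), len(y))

        assert exact_identity(a, a) == 1.0
        assert exact_identity(a, c) < 0.8
        clusters = cluster_transcripts({"A": a, "B": a, "C": c}, identity_threshold=0.8)
        parts = sorted(sorted(cl.member_ids) for cl in clusters)
        assert parts == [["A", "B"], ["C"]]

    def test_clusters_partition_input(self):
        rng = random.Random(3)
        seqs = {f"t{i}": _random_seq(rng, rng.randint(60, 200)) for i in range(20)}
        clusters = cluster_transcripts(seqs)
        seen = [m for cl in clusters for m in cl.member_ids]
        assert sorted(seen) == sorted(seqs)
        for cl in clusters:
            assert cl.representative_id in cl.member_ids

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            cluster_transcripts({"a": "ACGTX"})

    def test_empty_input_empty_output(self):
        assert cluster_transcripts({}) == []


class TestAggregate:
    def test_mean_over_hitting_members(self):
        cl = GeneCluster("g1", frozenset({"t1", "t2"}), "t1")
        s = aggregate_gene_hits(cl, [hit(q="t1", score=100), hit(q="t2", score=200)])
        assert s["P1"].avg_bit_score == 150

    def test_single_hitting_member_not_zero_filled(self):
        cl = GeneCluster("g1", frozenset({"t1", "t2"}), "t1")
        s = aggregate_gene_hits(cl, [hit(q="t1", acc="P2", score=80)])
        assert s["P2"].avg_bit_score == 80  # not 40

    def test_no_hits_empty_summary(self):
        cl = GeneCluster("g1", frozenset({"t1"}), "t1")
        assert aggregate_gene_hits(cl, []) == {}

    def test_invariant_under_duplicated_hit_rows(self):
        cl = GeneCluster("g1", frozenset({"t1", "t2"}), "t1")
        hits = [hit(q="t1", score=100), hit(q="t2", score=200)]
        once = aggregate_gene_hits(cl, hits)
        doubled = aggregate_gene_hits(cl, hits + hits)
        assert once["P1"].avg_bit_score == doubled["P1"].avg_bit_score == 150


class TestBestMatch:
    def test_restricted_to_human(self):
        cl = GeneCluster("g", frozenset({"t1"}), "t1")
        s = aggregate_gene_hits(
            cl,
            [
                hit(acc="P1", species="human", score=100, sig=1e-30),
                hit(acc="P2", species="human", score=90, sig=1e-40),
                hit(acc="P3", species="mouse", score=200, sig=1e-50),
            ],
        )
        assert human_best_match(s).subject_acc == "P1"

    def test_none_when_no_human_subject(self):
        cl = GeneCluster("g", frozenset({"t1"}), "t1")
        s = aggregate_gene_hits(cl, [hit(acc="P3", species="mouse")])
        assert human_best_match(s) is None

    def test_score_tie_broken_by_lower_sig(self):
        cl = GeneCluster("g", frozenset({"t1"}), "t1")
        s = aggregate_gene_hits(
            cl,
            [
                hit(acc="P1", score=100, sig=1e-30),
                hit(acc="P2", score=100, sig=1e-40),
            ],
        )
        assert human_best_match(s).subject_acc == "P2"

    def test_full_tie_broken_lexicographically(self):
        cl = GeneCluster("g", frozenset({"t1"}), "t1")
        s = aggregate_gene_hits(
            cl, [hit(acc="PB", score=100, sig=1e-30), hit(acc="PA", score=100, sig=1e-30)]
        )
        assert human_best_match(s).subject_acc == "PA"


class TestListMatch:
    def test_threshold_selects_strict_hits(self):
        cl = GeneCluster("g", frozenset({"t1"}), "t1")
        s = aggregate_gene_hits(
            cl,
            [
                hit(acc="P1", sig=1e-20),
                hit(acc="P2", sig=1e-16),
                hit(acc="P3", sig=1e-10),
            ],
        )
        assert list_match_annotation(s, 1e-15) == {"P1", "P2"}

    def test_threshold_one_keeps_all(self):
        cl = GeneCluster("g", frozenset({"t1"}), "t1")
        s = aggregate_gene_hits(cl, [hit(acc="P1", sig=0.5), hit(acc="P2", sig=1e-9)])
        assert list_match_annotation(s, 1.0) == {"P1", "P2"}

    def test_empty_summary_empty_set(self):
        assert list_match_annotation({}, 1e-15) == frozenset()


def test_best_match_member_of_list_match_when_strict():
    """When the best match clears the list cutoff it must appear in the list."""
    cl = GeneCluster("g1", frozenset({"t1"}), "t1")
    hits = [hit(acc="P1", score=300, sig=1e-30), hit(acc="P2", species="other", sig=1e-16)]
    ann = annotate_genes([cl], hits)["g1"]
    assert ann.best_match_acc == "P1"
    assert "P1" in ann.list_match
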