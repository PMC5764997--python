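"""Transcript-to-gene collapsing and alignment-hit-based gene annotation.

Transcripts are collapsed to genes at an 80% similarity threshold (a
greedy, longest-first clusterer standing in for CD-Hit; an externally
computed cluster map can be injected instead).  Hits are filtered to
eukaryotic subjects below a significance cutoff, then summarised per
gene by averaging scores over the member transcripts that hit each
subject.  Two annotations are derived per gene:

* the *human best match* — the human subject with the best average
  alignment score (ties: lowest average significance, then accession);
* the *list match* — every subject, any species, whose average
  significance clears a strict cutoff (default 1e-15), giving a broader
  shared annotation usable across distant species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import HitRecord

__all__ = [
    "GeneCluster",
    "SubjectSummary",
    "AnnotationRecord",
    "filter_hits",
    "cluster_transcripts",
    "aggregate_gene_hits",
    "human_best_match",
    "list_match_annotation",
    "annotate_genes",
    "hits_per_gene_diagnostic",
    "DEFAULT_TAXON_ALLOW",
]

#: Taxa accepted as eukaryotic in hit filtering; matched case-insensitively.
DEFAULT_TAXON_ALLOW = frozenset({"eukaryota", "eukaryote", "eukaryotic"})

#: Strict significance cutoff defining the list-match annotation.
LIST_MATCH_SIG = 1e-15

#: Permissive significance cutoff for considering a hit at all.
PERMISSIVE_SIG = 1e-2


@dataclass(frozen=True)
class GeneCluster:
    """A set of transcripts collapsed to one gene unit."""

    gene_id: str
    member_ids: frozenset[str]
    representative_id: str

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("GeneCluster must have at least one member")
        if self.representative_id not in self.member_ids:
            raise ValueError("representative_id must be a member of the cluster")


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject averages over the member transcripts hitting it."""

    subject_acc: str
    species: str
    avg_bit_score: float
    avg_sig_value: float
    n_members_hitting: int


@dataclass(frozen=True)
class AnnotationRecord:
    """Best-match and list-match annotation of one gene."""

    gene_id: str
    best_match_acc: str | None
    best_match_score: float | None
    best_match_sig: float | None
    list_match: frozenset[str]


def filter_hits(
    hits: Iterable[HitRecord],
    sig_threshold: float = PERMISSIVE_SIG,
    taxon_allow: Iterable[str] = DEFAULT_TAXON_ALLOW,
) -> list[HitRecord]:
    """Retain hits with ``sig_value <= sig_threshold`` and an allowed taxon.

    Hits to non-eukaryotic subjects are discarded regardless of score.
    The keep rule is inclusive at the threshold; order is preserved.
    """
    if sig_threshold <= 0:
        raise ValueError(f"sig_threshold must be > 0, got {sig_threshold}")
    allow = {t.lower() for t in taxon_allow}
    if not allow:
        raise ValueError("taxon allow-list must not be empty")
    return [
        h for h in hits if h.sig_value <= sig_threshold and h.subject_taxon.lower() in allow
    ]


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cluster_transcripts(
    sequences: Mapping[str, str],
    identity_threshold: float = 0.8,
    word_size: int = 8,
    gene_prefix: str = "gene",
) -> list[GeneCluster]:
    """Greedy longest-first clustering of nucleotide sequences.

    Sequences are sorted by descending length (ties by id) and each is
    assigned to the first existing cluster whose representative shares at
    least ``identity_threshold`` estimated identity, measured as k-mer
    containment of the shorter sequence in the representative; otherwise
    it founds a new cluster with itself as representative.  The result is
    a partition of the input.

    This is a fixture-grade stand-in for CD-Hit: adequate for collapsing
    near-identical transcript variants, not a general sequence clusterer.
    Externally computed cluster maps can be supplied to the pipeline
    instead (``cluster_map`` config key).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    valid = set("ACGTN")
    for tid, seq in sequences.items():
        bad = set(seq.upper()) - valid
        if bad:
            raise ValueError(f"sequence '{tid}' contains non-nucleotide symbols {sorted(bad)}")

    order = sorted(sequences, key=lambda t: (-len(sequences[t]), t))
    reps: list[str] = []
    rep_kmers: list[set[str]] = []
    members: list[list[str]] = []
    for tid in order:
        seq = sequences[tid].upper()
        km = _kmers(seq, word_size)
        placed = False
        for ci, rep_km in enumerate(rep_kmers):
            if not km:
                break
            containment = len(km & rep_km) / len(km)
            if containment >= identity_threshold:
                members[ci].append(tid)
                placed = True
                break
        if not placed:
            reps.append(tid)
            rep_kmers.append(km)
            members.append([tid])

    width = max(4, len(str(len(reps))))
    return [
        GeneCluster(
            gene_id=f"{gene_prefix}{i + 1:0{width}d}",
            member_ids=frozenset(mem),
            representative_id=rep,
        )
        for i, (rep, mem) in enumerate(zip(reps, members))
    ]


def aggregate_gene_hits(
    cluster: GeneCluster | Iterable[str],
    hits: Iterable[HitRecord],
) -> dict[str, SubjectSummary]:
    """Average bit score and significance per subject over a gene's members.

    For each subject hit by at least one member transcript, the mean is
    taken over the member transcripts that hit it; members lacking a hit
    to that subject contribute nothing (no zero-filling), so the summary
    is invariant under duplicating a member's hit rows.  A member hitting
    the same subject several times contributes its best (highest-score)
    hit once.
    """
    member_ids = cluster.member_ids if isinstance(cluster, GeneCluster) else set(cluster)
    # per (subject, member): keep the single best hit of that member
    best_per_pair: dict[tuple[str, str], HitRecord] = {}
    species_of: dict[str, str] = {}
    for h in hits:
        if h.query_id not in member_ids:
            continue
        key = (h.subject_acc, h.query_id)
        prev = best_per_pair.get(key)
        if prev is None or (h.bit_score, -h.sig_value) > (prev.bit_score, -prev.sig_value):
            best_per_pair[key] = h
        species_of[h.subject_acc] = h.subject_species
    per_subject: dict[str, list[HitRecord]] = {}
    for (acc, _member), h in best_per_pair.items():
        per_subject.setdefault(acc, []).append(h)
    out: dict[str, SubjectSummary] = {}
    for acc, hs in per_subject.items():
        out[acc] = SubjectSummary(
            subject_acc=acc,
            species=species_of[acc],
            avg_bit_score=sum(h.bit_score for h in hs) / len(hs),
            avg_sig_value=sum(h.sig_value for h in hs) / len(hs),
            n_members_hitting=len(hs),
        )
    return out


def human_best_match(
    summary: Mapping[str, SubjectSummary], human_label: str = "human"
) -> SubjectSummary | None:
    """The human subject with maximal average score.

    Ties are broken by minimal average significance, then by the
    lexicographically smallest accession, making the choice deterministic.
    Returns ``None`` when no human subject was hit.
    """
    human = [s for s in summary.values() if s.species == human_label]
    if not human:
        return None
    return min(human, key=lambda s: (-s.avg_bit_score, s.avg_sig_value, s.subject_acc))


def list_match_annotation(
    summary: Mapping[str, SubjectSummary], sig_threshold: float = LIST_MATCH_SIG
) -> frozenset[str]:
    """All subject accessions (any species) with average sig <= threshold."""
    if sig_threshold <= 0:
        raise ValueError(f"sig_threshold must be > 0, got {sig_threshold}")
    return frozenset(
        acc for acc, s in summary.items() if s.avg_sig_value <= sig_threshold
    )


def annotate_genes(
    clusters: Sequence[GeneCluster],
    hits: Sequence[HitRecord],
    *,
    list_sig_threshold: float = LIST_MATCH_SIG,
    human_label: str = "human",
) -> dict[str, AnnotationRecord]:
    """Best-match + list-match annotation for every gene cluster.

    ``hits`` must already be filtered (taxon allow-list, permissive
    significance cutoff).  Returns a gene_id -> AnnotationRecord map.
    """
    by_member: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_member.setdefault(h.query_id, []).append(h)
    out: dict[str, AnnotationRecord] = {}
    for cl in clusters:
        relevant = [h for m in sorted(cl.member_ids) for h in by_member.get(m, [])]
        summary = aggregate_gene_hits(cl, relevant)
        best = human_best_match(summary, human_label=human_label)
        out[cl.gene_id] = AnnotationRecord(
            gene_id=cl.gene_id,
            best_match_acc=best.subject_acc if best else None,
            best_match_score=best.avg_bit_score if best else None,
            best_match_sig=best.avg_sig_value if best else None,
            list_match=list_match_annotation(summary, list_sig_threshold),
        )
    return out


def hits_per_gene_diagnostic(annotations: Mapping[str, AnnotationRecord]) -> dict[str, float]:
    """Distribution summary of list-match sizes (sanity diagnostic only).

    Real transcriptome annotations typically carry from one up to
    hundreds of hits per gene with a mean around 15; a wildly different
    mean usually signals threshold or taxon-filter misconfiguration.
    """
    sizes = [len(a.list_match) for a in annotations.values()]
    if not sizes:
        return {"n_genes": 0, "mean": float("nan"), "max": float("nan")}
    return {
        "n_genes": float(len(sizes)),
        "mean": sum(sizes) / len(sizes),
        "max": float(max(sizes)),
    }


def annotation_table(annotations: Mapping[str, AnnotationRecord]) -> pd.DataFrame:
    """Tabular form: gene_id, best-match fields, semicolon-joined list match."""
    rows = []
    for gid in sorted(annotations):
        a = annotations[gid]
        rows.append(
            {
                "gene_id": a.gene_id,
                "best_match_acc": a.best_match_acc or "",
                "best_match_score": a.best_match_score if a.best_match_score is not None else "",
                "best_match_sig": a.best_match_sig if a.best_match_sig is not None else "",
                "list_match": ";".join(sorted(a.list_match)),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "best_match_acc", "best_match_score", "best_match_sig", "list_match"]
    )
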