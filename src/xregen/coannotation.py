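"""Cross-species gene correspondence through shared reference-database hits.

Two modes:

* **best-match** — genes from different species are linked when they carry
  the same human best-match accession; groups of species sharing an
  accession feed Venn-style intersection counts.
* **list-match** — genes are linked when their strict-cutoff hit lists
  overlap by more than a threshold fraction of the smaller list (strict
  ``>``, default 0.8).  Links may be many-to-many; ambiguity is kept, not
  resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import AnnotationRecord

__all__ = [
    "CoAnnotationMap",
    "coannotate_best",
    "coannotate_list",
    "venn_counts",
    "intersect_de",
]


@dataclass
class CoAnnotationMap:
    """Cross-species links between genes.

    ``pairs`` holds orientation-free links as ``((species_a, gene_a),
    (species_b, gene_b))`` tuples with the two endpoints sorted, so each
    link is recorded once.  ``accession_groups`` (best-match mode only)
    maps each shared accession to the set of species carrying it.
    """

    mode: str
    pairs: set[tuple[tuple[str, str], tuple[str, str]]] = field(default_factory=set)
    annotated_genes: dict[str, set[str]] = field(default_factory=dict)
    accession_groups: dict[str, frozenset[str]] = field(default_factory=dict)

    def add_pair(self, a: tuple[str, str], b: tuple[str, str]) -> None:
        self.pairs.add(tuple(sorted((a, b))))  # type: ignore[arg-type]

    def linked(self, a: tuple[str, str], b: tuple[str, str]) -> bool:
        return tuple(sorted((a, b))) in self.pairs


def coannotate_best(
    annotations: Mapping[str, Mapping[str, AnnotationRecord]],
) -> CoAnnotationMap:
    """Link genes across species sharing an identical best-match accession.

    ``annotations`` maps species -> (gene_id -> AnnotationRecord); at
    least two species are required.  Also records, per human accession,
    the set of species carrying it (for intersection counting).
    """
    if len(annotations) < 2:
        raise ValueError("co-annotation requires at least two species")
    cmap = CoAnnotationMap(mode="best_match")
    acc_to_genes: dict[str, list[tuple[str, str]]] = {}
    for species, ann in annotations.items():
        annotated = set()
        for gid, rec in ann.items():
            if rec.best_match_acc is not None:
                annotated.add(gid)
                acc_to_genes.setdefault(rec.best_match_acc, []).append((species, gid))
        cmap.annotated_genes[species] = annotated
    for acc, carriers in acc_to_genes.items():
        species_set = frozenset(sp for sp, _ in carriers)
        cmap.accession_groups[acc] = species_set
        for (sp_a, g_a), (sp_b, g_b) in combinations(carriers, 2):
            if sp_a != sp_b:
                cmap.add_pair((sp_a, g_a), (sp_b, g_b))
    return cmap


def list_overlap(list_a: frozenset[str], list_b: frozenset[str]) -> float:
    """Fraction of the smaller list shared with the other; 0 if either empty."""
    if not list_a or not list_b:
        return 0.0
    return len(list_a & list_b) / min(len(list_a), len(list_b))


def coannotate_list(
    ann_a: Mapping[str, AnnotationRecord],
    ann_b: Mapping[str, AnnotationRecord],
    *,
    species_a: str = "a",
    species_b: str = "b",
    overlap_threshold: float = 0.8,
) -> CoAnnotationMap:
    """Link genes whose list-match annotations overlap strictly above threshold.

    The overlap is ``|L_a & L_b| / min(|L_a|, |L_b|)`` over non-empty
    lists and the comparison is strict (exactly 0.8 does not link at the
    default).  Many-to-many links are kept.  Inverted-index construction
    keeps this near-linear in the total list size rather than quadratic
    in gene count.
    """
    if not 0 < overlap_threshold <= 1:
        raise ValueError(f"overlap_threshold must be in (0, 1], got {overlap_threshold}")
    cmap = CoAnnotationMap(mode="list_match")
    cmap.annotated_genes[species_a] = {g for g, r in ann_a.items() if r.list_match}
    cmap.annotated_genes[species_b] = {g for g, r in ann_b.items() if r.list_match}
    index_b: dict[str, list[str]] = {}
    for gid_b, rec_b in ann_b.items():
        for acc in rec_b.list_match:
            index_b.setdefault(acc, []).append(gid_b)
    for gid_a, rec_a in ann_a.items():
        if not rec_a.list_match:
            continue
        candidates: set[str] = set()
        for acc in rec_a.list_match:
            candidates.update(index_b.get(acc, ()))
        for gid_b in candidates:
            if list_overlap(rec_a.list_match, ann_b[gid_b].list_match) > overlap_threshold:
                cmap.add_pair((species_a, gid_a), (species_b, gid_b))
    return cmap


def venn_counts(cmap: CoAnnotationMap) -> dict[frozenset[str], int]:
    """Number of shared accessions exactly covering each species subset.

    Best-match mode only: every accession carried by at least one species
    is assigned to the region of the Venn diagram matching exactly its
    carrier set, so regions are disjoint and sum to the union size.
    """
    if cmap.mode != "best_match":
        raise ValueError("venn_counts requires a best-match CoAnnotationMap")
    out: dict[frozenset[str], int] = {}
    for _acc, species_set in cmap.accession_groups.items():
        out[species_set] = out.get(species_set, 0) + 1
    return out


def coannotated_accessions(cmap: CoAnnotationMap, species: Iterable[str]) -> set[str]:
    """Accessions carried by every listed species (best-match mode)."""
    wanted = set(species)
    return {
        acc for acc, grp in cmap.accession_groups.items() if wanted <= grp
    }


def intersect_de(
    coannotated: Iterable[str],
    de_sets: Mapping[str, set[str]],
) -> set[str]:
    """Accessions co-annotated and DE in every species.

    ``coannotated`` is the accession group shared by all species (e.g.
    from :func:`coannotated_accessions`); ``de_sets`` maps species to the
    accessions of its DE genes (best-match accession of genes DE at >= 1
    time point).
    """
    result = set(coannotated)
    for _species, de in de_sets.items():
        result &= de
    return result


def venn_table(counts: Mapping[frozenset[str], int]) -> pd.DataFrame:
    """Venn region counts as a sorted table with a +/- flag per species."""
    species = sorted({sp for grp in counts for sp in grp})
    rows = []
    for grp in sorted(counts, key=lambda g: (len(g), sorted(g))):
        row = {sp: ("+" if sp in grp else "-") for sp in species}
        row["n_accessions"] = counts[grp]
        rows.append(row)
    return pd.DataFrame(rows, columns=[*species, "n_accessions"])
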