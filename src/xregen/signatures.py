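"""Immune and EMT gene-signature matching across species.

Signatures (macrophage, neutrophil, EMT, adherens junction) arrive as
plain accession lists from several sources.  Three operations combine
and project them:

* consensus over per-dataset DE lists (e.g. an EMT gene must be DE in at
  least two of four murine and three of eight human datasets);
* shared membership across source lists (genes on >= k lists);
* projection onto species annotations, producing a presence/DE matrix:
  for each signature accession and species, whether it is reachable via
  the human best-match or only the broader list-match annotation, and
  whether any matching gene is differentially expressed.

A reciprocal-best-hit filter provides annotation-free correspondence
between two transcriptomes for genes missing from the reference
database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import AnnotationRecord
from .io_formats import HitRecord

__all__ = [
    "SignatureSet",
    "CELL_STATES",
    "consensus_signature",
    "shared_members",
    "match_signature",
    "reciprocal_orthologs",
]

#: Ordered cell states of a signature matrix, weakest to strongest.
CELL_STATES = ("absent", "present_list", "present_best", "de_list", "de_best")


def _norm(symbol: str) -> str:
    """Case/whitespace normalization for cross-list gene-symbol matching.

    Human and murine symbol conventions differ only by case (MARCO vs
    Marco); lists are compared after uppercasing and stripping.
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class SignatureSet:
    """A named signature with provenance of each member accession."""

    name: str
    members: frozenset[str]
    source_lists: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source_lists:
            universe = frozenset().union(*self.source_lists.values())
            if not self.members <= universe:
                extra = sorted(self.members - universe)
                raise ValueError(f"members not in any source list: {extra[:5]}")


def consensus_signature(
    per_dataset_de_lists: Mapping[str, Mapping[str, Iterable[str]]],
    min_support: Mapping[str, int],
    name: str = "consensus",
) -> SignatureSet:
    """Consensus DE signature over grouped per-dataset DE lists.

    ``per_dataset_de_lists`` maps group name (e.g. "murine", "human") to
    its named dataset lists; an accession enters the signature iff it
    appears in at least ``min_support[group]`` datasets of its group.
    The union over groups is returned with per-source provenance.
    Thresholds of 1 reduce to the plain union; thresholds equal to the
    group size to the group-wise intersection.
    """
    members: set[str] = set()
    sources: dict[str, frozenset[str]] = {}
    for group, datasets in per_dataset_de_lists.items():
        if group not in min_support:
            raise ValueError(f"no min_support threshold for group '{group}'")
        k = min_support[group]
        if k < 1 or k > len(datasets):
            raise ValueError(
                f"min_support for '{group}' must be in [1, {len(datasets)}], got {k}"
            )
        support: dict[str, int] = {}
        for ds_name, accs in datasets.items():
            normed = frozenset(_norm(a) for a in accs)
            sources[f"{group}/{ds_name}"] = normed
            for a in normed:
                support[a] = support.get(a, 0) + 1
        members.update(a for a, n in support.items() if n >= k)
    return SignatureSet(name=name, members=frozenset(members), source_lists=sources)


def shared_members(lists: Mapping[str, Iterable[str]], k: int = 2) -> set[str]:
    """Accessions present in at least ``k`` of the named lists.

    Matching is case-insensitive after symbol normalization; the
    returned accessions are in normalized (uppercase) form.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    support: dict[str, int] = {}
    for _name, accs in lists.items():
        for a in {_norm(x) for x in accs}:
            support[a] = support.get(a, 0) + 1
    return {a for a, n in support.items() if n >= k}


def match_signature(
    sig: SignatureSet,
    annotations: Mapping[str, Mapping[str, AnnotationRecord]],
    de_flags: Mapping[str, Mapping[str, bool]],
    mode: str = "best",
) -> pd.DataFrame:
    """Project a signature onto per-species annotations.

    Returns a DataFrame indexed by signature accession with one column
    per species holding a cell state:

    * ``absent`` — no gene of the species reaches the accession;
    * ``present_best`` / ``present_list`` — reachable via best-match or
      (list mode) via the broader list-match annotation;
    * ``de_best`` / ``de_list`` — additionally, at least one matching
      gene is DE during regeneration.

    ``mode="best"`` considers only best-match accessions; ``"list"``
    considers list-match sets (an accession counts as DE if ANY gene
    whose list contains it is DE — the permissive reading).
    """
    if mode not in ("best", "list"):
        raise ValueError(f"mode must be 'best' or 'list', got '{mode}'")
    species_names = sorted(annotations)
    rows: dict[str, dict[str, str]] = {}
    for acc in sorted(sig.members):
        row: dict[str, str] = {}
        for sp in species_names:
            ann = annotations[sp]
            de = de_flags.get(sp, {})
            matching: list[str] = []
            for gid, rec in ann.items():
                if mode == "best":
                    found = rec.best_match_acc is not None and _norm(rec.best_match_acc) == acc
                else:
                    found = acc in {_norm(a) for a in rec.list_match}
                if found:
                    matching.append(gid)
            if not matching:
                row[sp] = "absent"
            elif any(de.get(g, False) for g in matching):
                row[sp] = "de_best" if mode == "best" else "de_list"
            else:
                row[sp] = "present_best" if mode == "best" else "present_list"
        rows[acc] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=species_names)
    df.index.name = "accession"
    return df


def _best_passing_hits(
    hits: Iterable[HitRecord], min_coverage: float, min_identity: float
) -> dict[str, str]:
    """Top passing subject per query (score, then sig, then accession)."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.query_coverage is None or h.identity_frac is None:
            raise ValueError(
                "reciprocal ortholog filtering needs query_coverage and identity_frac "
                "columns; supply a hit-table dialect that maps them"
            )
        if h.query_coverage < min_coverage or h.identity_frac < min_identity:
            continue
        prev = best.get(h.query_id)
        if prev is None or (-h.bit_score, h.sig_value, h.subject_acc) < (
            -prev.bit_score,
            prev.sig_value,
            prev.subject_acc,
        ):
            best[h.query_id] = h
    return {q: h.subject_acc for q, h in best.items()}


def reciprocal_orthologs(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    min_coverage: float = 0.4,
    min_identity: float = 0.6,
) -> set[tuple[str, str]]:
    """Reciprocal-best-hit gene pairs between two transcriptomes.

    A pair (g_a, g_b) is retained iff g_b is g_a's top-scoring hit
    passing the coverage/identity thresholds in the a->b table and g_a
    is g_b's top passing hit in b->a.  Defaults sit inside the ranges
    typically used for cross-phyla nucleotide matches (coverage 0.3-0.5,
    identity 0.5-0.7); scan the ranges when calibrating a new species
    pair.
    """
    if not 0 < min_coverage <= 1 or not 0 < min_identity <= 1:
        raise ValueError("thresholds must be in (0, 1]")
    best_ab = _best_passing_hits(hits_ab, min_coverage, min_identity)
    best_ba = _best_passing_hits(hits_ba, min_coverage, min_identity)
    return {
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    }
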