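"""Readers and writers for the external formats the pipeline touches.

Every format is plain text: tab-separated alignment hit tables (BLAST
``outfmt 6`` compatible through a configurable column map), TSV count
matrices (genes x time points, hours post injury), one-accession-per-line
gene lists, FASTA transcript files, and JSON run manifests.  Readers
validate aggressively and report the offending row/cell, because the
downstream statistics silently absorb malformed input otherwise.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HitRecord",
    "CountMatrix",
    "HitTableDialect",
    "FormatError",
    "ValidationError",
    "read_hit_table",
    "read_counts",
    "read_gene_list",
    "read_fasta",
    "write_report",
]


class FormatError(ValueError):
    """Structural problem with an input file (missing column, bad header)."""


class ValidationError(ValueError):
    """A well-formed file carrying values that violate an invariant."""


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit of a query transcript against a reference protein.

    ``sig_value`` is the aligner's significance value (an E-value for
    BLAST); it is treated opaquely and thresholds are applied to it
    directly.  ``query_coverage`` and ``identity_frac`` are optional and
    only needed for reciprocal-best-hit orthology filtering.
    """

    query_id: str
    subject_acc: str
    subject_taxon: str
    subject_species: str
    bit_score: float
    sig_value: float
    query_coverage: float | None = None
    identity_frac: float | None = None

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValidationError(f"bit_score must be >= 0, got {self.bit_score}")
        if self.sig_value < 0:
            raise ValidationError(f"sig_value must be >= 0, got {self.sig_value}")
        for name in ("query_coverage", "identity_frac"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


#: Default column map for a 12-column BLAST outfmt-6 table augmented with
#: taxon/species columns.  Keys are HitRecord field names, values are
#: 0-based column indices; ``None`` marks an absent optional column.
DEFAULT_DIALECT: dict[str, int | None] = {
    "query_id": 0,
    "subject_acc": 1,
    "subject_taxon": 2,
    "subject_species": 3,
    "bit_score": 4,
    "sig_value": 5,
    "query_coverage": None,
    "identity_frac": None,
}

HitTableDialect = Mapping[str, int | None]

_MANDATORY_HIT_FIELDS = (
    "query_id",
    "subject_acc",
    "subject_taxon",
    "subject_species",
    "bit_score",
    "sig_value",
)


def read_hit_table(path: str | Path, dialect: HitTableDialect | None = None) -> list[HitRecord]:
    """Read a tab-separated alignment hit table into ``HitRecord`` objects.

    Parameters
    ----------
    path:
        Tab-separated file, one hit per line; ``#`` comment lines allowed.
    dialect:
        Field-name -> column-index map; defaults to :data:`DEFAULT_DIALECT`.

    Raises
    ------
    FormatError
        If a mandatory field is missing from the dialect or a row is too
        short to supply it.
    ValidationError
        If a value violates a HitRecord invariant; the message names the
        1-based row number.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    for name in _MANDATORY_HIT_FIELDS:
        if dialect.get(name) is None:
            raise FormatError(f"dialect missing mandatory column for field '{name}'")

    records: list[HitRecord] = []
    with open(path, "r", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            kwargs: dict[str, object] = {}
            for name, idx in dialect.items():
                if idx is None:
                    continue
                if idx >= len(cols):
                    raise FormatError(
                        f"row {lineno}: expected column {idx + 1} for field '{name}', "
                        f"row has only {len(cols)} columns"
                    )
                kwargs[name] = cols[idx]
            try:
                rec = HitRecord(
                    query_id=str(kwargs["query_id"]),
                    subject_acc=str(kwargs["subject_acc"]),
                    subject_taxon=str(kwargs["subject_taxon"]),
                    subject_species=str(kwargs["subject_species"]),
                    bit_score=float(kwargs["bit_score"]),  # type: ignore[arg-type]
                    sig_value=float(kwargs["sig_value"]),  # type: ignore[arg-type]
                    query_coverage=(
                        float(kwargs["query_coverage"]) if "query_coverage" in kwargs else None  # type: ignore[arg-type]
                    ),
                    identity_frac=(
                        float(kwargs["identity_frac"]) if "identity_frac" in kwargs else None  # type: ignore[arg-type]
                    ),
                )
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"row {lineno}: {exc}") from exc
            records.append(rec)
    return records


@dataclass
class CountMatrix:
    """Raw counts for one species: genes x time points (hours post injury).

    The first time point is the pre-/immediately-post-injury baseline.
    Counts are non-negative integers; time points strictly increase.
    ``gene_length_bp`` (optional) enables rpkm-based expression filtering.
    """

    species: str
    gene_ids: list[str]
    time_points_h: np.ndarray
    counts: np.ndarray
    gene_length_bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_points_h = np.asarray(self.time_points_h, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D genes x time matrix")
        n_genes, n_times = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError("gene_ids length does not match counts rows")
        if len(self.time_points_h) != n_times:
            raise ValidationError("time_points_h length does not match counts columns")
        if len(set(self.gene_ids)) != n_genes:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if np.any(np.diff(self.time_points_h) <= 0):
            raise ValidationError("time_points_h must be strictly increasing")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            if not np.all(np.equal(np.mod(as_int, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.gene_length_bp is not None:
            self.gene_length_bp = np.asarray(self.gene_length_bp, dtype=float)
            if len(self.gene_length_bp) != n_genes:
                raise ValidationError("gene_length_bp length does not match counts rows")
            if np.any(self.gene_length_bp <= 0):
                raise ValidationError("gene_length_bp must be positive")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_times(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [_format_time(t) for t in self.time_points_h]
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=cols)

    def write(self, path: str | Path) -> None:
        """Write as TSV (first column ``gene_id``, header = hours)."""
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", lineterminator="\n")


def _format_time(t: float) -> str:
    return f"{t:g}"


def read_counts(path: str | Path, species: str | None = None) -> CountMatrix:
    """Read a TSV count matrix (header row = time points in hours).

    The first column holds gene ids; remaining column labels must parse
    as strictly increasing numbers.  Non-integer counts and duplicate
    gene ids are rejected with the offending cell/row named.
    """
    path = Path(path)
    with open(path, "r", newline="") as fh:
        header = fh.readline().rstrip("\r\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        head_cols = header.split("\t")
        if len(head_cols) < 2:
            raise FormatError(f"{path}: header must contain gene-id column plus time points")
        try:
            times = np.array([float(c) for c in head_cols[1:]], dtype=float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric time point in header: {exc}") from exc
        if np.any(np.diff(times) <= 0):
            raise FormatError(f"{path}: time points not strictly increasing: {times.tolist()}")

        gene_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(head_cols):
                raise FormatError(
                    f"{path}: row {lineno} has {len(cols)} columns, expected {len(head_cols)}"
                )
            gene_ids.append(cols[0])
            row: list[int] = []
            for j, cell in enumerate(cols[1:], start=1):
                try:
                    value = float(cell)
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}: row {lineno}, column {j + 1}: non-numeric count '{cell}'"
                    ) from exc
                if value != int(value):
                    raise ValidationError(
                        f"{path}: row {lineno}, column {j + 1}: non-integer count '{cell}'"
                    )
                row.append(int(value))
            rows.append(row)

    counts = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(times)), dtype=np.int64)
    return CountMatrix(
        species=species if species is not None else path.stem,
        gene_ids=gene_ids,
        time_points_h=times,
        counts=counts,
    )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text accession list: one per line, '#' comments allowed.

    Returns a deduplicated, order-preserving list with case preserved.
    An empty result triggers a warning (likely a mis-pointed path).
    """
    seen: dict[str, None] = {}
    with open(path, "r", newline="") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                seen.setdefault(line)
    if not seen:
        warnings.warn(f"gene list {path} is empty after comment/blank removal", stacklevel=2)
    return list(seen)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences as an id -> sequence map (uppercased)."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate FASTA id '{rec.id}'")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write one TSV per named table plus a JSON run manifest.

    Rows are sorted by the first column so reruns on identical inputs are
    byte-identical.  The manifest records a config hash, the seed and per
    table row counts; it contains no timestamps by design (determinism).
    Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "config_sha256": _hash_config(config),
        "tables": {},
    }
    for name in sorted(tables):
        df = tables[name]
        if len(df.columns) > 0 and len(df) > 0:
            df = df.sort_values(by=list(df.columns[:1]), kind="mergesort").reset_index(drop=True)
        dest = out_dir / f"{name}.tsv"
        df.to_csv(dest, sep="\t", index=False, lineterminator="\n", float_format="%.10g")
        manifest["tables"][name] = {"path": dest.name, "n_rows": int(len(df))}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _hash_config(config: Mapping | None) -> str | None:
    if config is None:
        return None
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
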