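"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order: per-species annotation -> cross-species
co-annotation -> differential expression -> temporal patterns ->
signature matrices, ending with a TSV/manifest report.  The run is
deterministic: identical config and inputs give byte-identical outputs.

The YAML run config houses the global constants of the analysis: the
permissive (1e-2) and strict (1e-15) significance cutoffs, the 80%
clustering-identity and 80% list-overlap thresholds, the >20-counts /
>1-rpkm expression filter, |log2FC| thresholds (2 by default, 0.5 for
the hydra-like species) and alpha 0.05.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import coannotation as co_mod
from . import de_analysis as de_mod
from . import signatures as sig_mod
from . import temporal as tmp_mod
from .io_formats import read_counts, read_gene_list, read_hit_table, write_report

__all__ = ["SpeciesConfig", "RunConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("xregen")


@dataclass
class SpeciesConfig:
    """Input paths and per-species overrides."""

    name: str
    hits: Path
    counts: Path
    fc_threshold: float | None = None
    early_indices: tuple[int, ...] | None = None
    late_indices: tuple[int, ...] | None = None
    recovery_index: int | None = None
    cluster_map: Path | None = None


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration."""

    species: dict[str, SpeciesConfig]
    permissive_sig: float = 1e-2
    list_sig: float = 1e-15
    overlap_threshold: float = 0.8
    taxon_allow: tuple[str, ...] = tuple(sorted(ann_mod.DEFAULT_TAXON_ALLOW))
    de: de_mod.DEConfig = field(default_factory=de_mod.DEConfig)
    recovery_tol: float = 0.5
    k_clusters: int = 4
    signature_lists: dict[str, Path] = field(default_factory=dict)
    out_dir: Path = Path("xregen_out")
    seed: int = 0


_SPECIES_KEYS = {
    "hits",
    "counts",
    "fc_threshold",
    "early_indices",
    "late_indices",
    "recovery_index",
    "cluster_map",
}
_TOP_KEYS = {"species", "annotation", "de", "temporal", "signatures", "out_dir", "seed"}
_ANN_KEYS = {"permissive_sig", "list_sig", "overlap_threshold", "taxon_allow"}
_DE_KEYS = {"fc_threshold", "alpha", "min_count", "min_rpkm", "dispersion", "pseudocount"}
_TMP_KEYS = {"recovery_tol", "k_clusters"}


def _reject_unknown(d: Mapping[str, Any], allowed: set[str], ctx: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {ctx}: {sorted(unknown)}")


def _in_range(value: float, lo: float, hi: float, name: str) -> float:
    if not (lo < value <= hi):
        raise ValueError(f"{name} must be in ({lo}, {hi}], got {value}")
    return float(value)


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")
    base = path.parent

    species_raw = raw.get("species") or {}
    if not species_raw:
        raise ValueError("config must declare at least one species")
    species: dict[str, SpeciesConfig] = {}
    for name, sd in species_raw.items():
        sd = sd or {}
        _reject_unknown(sd, _SPECIES_KEYS, f"species '{name}'")
        for req in ("hits", "counts"):
            if req not in sd:
                raise ValueError(f"species '{name}' missing required key '{req}'")
        hits = base / sd["hits"]
        counts = base / sd["counts"]
        for p in (hits, counts):
            if not p.exists():
                raise ValueError(f"species '{name}': input path does not exist: {p}")
        species[name] = SpeciesConfig(
            name=name,
            hits=hits,
            counts=counts,
            fc_threshold=sd.get("fc_threshold"),
            early_indices=tuple(sd["early_indices"]) if "early_indices" in sd else None,
            late_indices=tuple(sd["late_indices"]) if "late_indices" in sd else None,
            recovery_index=sd.get("recovery_index"),
            cluster_map=(base / sd["cluster_map"]) if sd.get("cluster_map") else None,
        )

    ann = raw.get("annotation") or {}
    _reject_unknown(ann, _ANN_KEYS, "annotation")
    de_raw = raw.get("de") or {}
    _reject_unknown(de_raw, _DE_KEYS, "de")
    tmp = raw.get("temporal") or {}
    _reject_unknown(tmp, _TMP_KEYS, "temporal")
    sig_raw = raw.get("signatures") or {}
    _reject_unknown(sig_raw, {"lists"}, "signatures")

    sig_lists: dict[str, Path] = {}
    for name, p in (sig_raw.get("lists") or {}).items():
        full = base / p
        if not full.exists():
            raise ValueError(f"signature list '{name}': path does not exist: {full}")
        sig_lists[name] = full

    cfg = RunConfig(
        species=species,
        permissive_sig=_in_range(ann.get("permissive_sig", 1e-2), 0, 1, "permissive_sig"),
        list_sig=_in_range(ann.get("list_sig", 1e-15), 0, 1, "list_sig"),
        overlap_threshold=_in_range(
            ann.get("overlap_threshold", 0.8), 0, 1, "overlap_threshold"
        ),
        taxon_allow=tuple(ann.get("taxon_allow", sorted(ann_mod.DEFAULT_TAXON_ALLOW))),
        de=de_mod.DEConfig(
            fc_threshold=de_raw.get("fc_threshold", 2.0),
            alpha=de_raw.get("alpha", 0.05),
            min_count=de_raw.get("min_count", 20),
            min_rpkm=de_raw.get("min_rpkm", 1.0),
            dispersion=de_raw.get("dispersion", 0.1),
            pseudocount=de_raw.get("pseudocount", 0.5),
        ),
        recovery_tol=float(tmp.get("recovery_tol", 0.5)),
        k_clusters=int(tmp.get("k_clusters", 4)),
        signature_lists=sig_lists,
        out_dir=base / raw.get("out_dir", "xregen_out"),
        seed=int(raw.get("seed", 0)),
    )
    return cfg


def _load_clusters(sp: SpeciesConfig, gene_ids: list[str]) -> list[ann_mod.GeneCluster]:
    """Cluster map from file, or singleton clusters (one gene per id)."""
    if sp.cluster_map is not None:
        df = pd.read_csv(sp.cluster_map, sep="\t", names=["transcript_id", "gene_id"])
        grouped: dict[str, list[str]] = {}
        for t, g in zip(df["transcript_id"], df["gene_id"]):
            grouped.setdefault(str(g), []).append(str(t))
        return [
            ann_mod.GeneCluster(
                gene_id=g, member_ids=frozenset(ms), representative_id=sorted(ms)[0]
            )
            for g, ms in sorted(grouped.items())
        ]
    return [
        ann_mod.GeneCluster(gene_id=g, member_ids=frozenset([g]), representative_id=g)
        for g in gene_ids
    ]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write all result tables plus a manifest."""
    t0 = time.perf_counter()
    tables: dict[str, pd.DataFrame] = {}
    annotations: dict[str, dict[str, ann_mod.AnnotationRecord]] = {}
    de_tables: dict[str, de_mod.DETable] = {}
    counts_by_sp = {}

    for name, sp in cfg.species.items():
        log.info("stage annotate: %s", name)
        hits = read_hit_table(sp.hits)
        hits = ann_mod.filter_hits(hits, cfg.permissive_sig, cfg.taxon_allow)
        counts = read_counts(sp.counts, species=name)
        counts_by_sp[name] = counts
        gene_ids = sorted(set(counts.gene_ids) | {h.query_id for h in hits})
        clusters = _load_clusters(sp, gene_ids)
        annotations[name] = ann_mod.annotate_genes(
            clusters, hits, list_sig_threshold=cfg.list_sig
        )
        tables[f"annotation_{name}"] = ann_mod.annotation_table(annotations[name])

        log.info("stage de: %s", name)
        de_cfg = cfg.de
        if sp.fc_threshold is not None:
            de_cfg = de_mod.DEConfig(
                fc_threshold=sp.fc_threshold,
                alpha=cfg.de.alpha,
                min_count=cfg.de.min_count,
                min_rpkm=cfg.de.min_rpkm,
                dispersion=cfg.de.dispersion,
                pseudocount=cfg.de.pseudocount,
            )
        de_tables[name] = de_mod.run_de(counts, de_cfg)
        tables[f"de_{name}"] = de_tables[name].table

        log.info("stage temporal: %s", name)
        phases = tmp_mod.assign_phases(
            counts.time_points_h,
            species=name,
            early_indices=sp.early_indices,
            late_indices=sp.late_indices,
            recovery_index=sp.recovery_index,
        )
        det = de_tables[name]
        wide_fc = det.table.pivot(index="gene_id", columns="time_h", values="log2fc")
        wide_de = det.table.pivot(index="gene_id", columns="time_h", values="is_de")
        wide_fc = wide_fc.sort_index()
        wide_de = wide_de.loc[wide_fc.index]
        patt = tmp_mod.classify_all(
            wide_fc.to_numpy(),
            wide_de.to_numpy(dtype=bool),
            list(wide_fc.index),
            phases,
            cfg.recovery_tol,
        )
        tables[f"patterns_{name}"] = patt

        de_mask = wide_de.to_numpy(dtype=bool).any(axis=1)
        if int(de_mask.sum()) >= cfg.k_clusters:
            labels, _means, _const = tmp_mod.cluster_profiles(
                wide_fc.to_numpy()[de_mask], k=cfg.k_clusters
            )
            tables[f"profile_clusters_{name}"] = pd.DataFrame(
                {"gene_id": np.array(wide_fc.index)[de_mask], "cluster": labels}
            )

    if len(cfg.species) >= 2:
        log.info("stage coannotate")
        cmap = co_mod.coannotate_best(annotations)
        venn = co_mod.venn_counts(cmap)
        tables["coannotation_venn"] = co_mod.venn_table(venn)
        all_species = sorted(cfg.species)
        shared = co_mod.coannotated_accessions(cmap, all_species)
        de_acc_sets = {
            name: {
                annotations[name][g].best_match_acc
                for g in det.de_genes()
                if annotations[name].get(g) and annotations[name][g].best_match_acc
            }
            for name, det in de_tables.items()
        }
        common_de = sorted(co_mod.intersect_de(shared, de_acc_sets))
        tables["common_de"] = pd.DataFrame({"accession": common_de})

        pair_rows = []
        names = sorted(cfg.species)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                lmap = co_mod.coannotate_list(
                    annotations[a],
                    annotations[b],
                    species_a=a,
                    species_b=b,
                    overlap_threshold=cfg.overlap_threshold,
                )
                pair_rows.append({"species_a": a, "species_b": b, "n_links": len(lmap.pairs)})
        tables["coannotation_list_pairs"] = pd.DataFrame(pair_rows)
    else:
        log.info("stage coannotate: skipped (single species)")

    if cfg.signature_lists:
        log.info("stage signatures")
        lists = {name: read_gene_list(p) for name, p in cfg.signature_lists.items()}
        members = sig_mod.shared_members(lists, k=1)
        sig = sig_mod.SignatureSet(
            name="signature",
            members=frozenset(members),
            source_lists={n: frozenset(a.upper() for a in accs) for n, accs in lists.items()},
        )
        de_flags = {name: det.gene_de for name, det in de_tables.items()}
        for mode in ("best", "list"):
            mat = sig_mod.match_signature(sig, annotations, de_flags, mode=mode)
            tables[f"signature_matrix_{mode}"] = mat.reset_index()

    manifest = write_report(
        tables,
        cfg.out_dir,
        config={
            "species": sorted(cfg.species),
            "permissive_sig": cfg.permissive_sig,
            "list_sig": cfg.list_sig,
            "overlap_threshold": cfg.overlap_threshold,
            "de": {
                "fc_threshold": cfg.de.fc_threshold,
                "alpha": cfg.de.alpha,
                "min_count": cfg.de.min_count,
                "dispersion": cfg.de.dispersion,
                "pseudocount": cfg.de.pseudocount,
            },
            "recovery_tol": cfg.recovery_tol,
            "k_clusters": cfg.k_clusters,
        },
        seed=cfg.seed,
    )
    log.info("pipeline complete in %.1f s", time.perf_counter() - t0)
    return manifest
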