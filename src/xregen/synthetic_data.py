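"""Seeded multi-species fixtures with planted ground truth.

Emulates the data the pipeline is built for: three regenerating species
sampled on heterogeneous time grids (a hydra-like dense early grid, a
planarian-like hourly grid, a sea-cucumber-like day-scale grid), each
with

* an alignment hit table against a synthetic reference-protein universe
  (human/mouse/other-eukaryote/bacteria accessions), with ortholog
  triplets planted as shared hit lists, Poisson decoy hits, and a
  bacterial-hit fraction to exercise taxon filtering;
* a raw count time course with NB noise (variance = mu + phi mu^2) and
  planted EU/ED/LU/LD fold-change pulses at stated effect sizes;
* signature lists with controlled overlap and per-dataset DE lists with
  known consensus membership.

Every generator is bit-reproducible under a fixed seed, and a
:class:`TruthTable` records what was planted so downstream recovery can
be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, HitRecord

__all__ = [
    "GeneratorConfig",
    "Universe",
    "TruthTable",
    "DEFAULT_TIME_GRIDS",
    "generate_reference_universe",
    "generate_hit_tables",
    "generate_timecourse_counts",
    "generate_signature_fixture",
    "generate_reciprocal_fixture",
    "write_fixture",
]

#: Hour grids mirroring the real sampling designs: dense early sampling
#: for the hydra-like species, regular sampling for the planarian-like
#: one, and day-denominated sampling (converted to hours) for the
#: sea-cucumber-like one, whose early phase has a single time point.
DEFAULT_TIME_GRIDS: dict[str, tuple[float, ...]] = {
    "hydra": (0.0, 0.5, 3.0, 6.0, 12.0, 24.0, 48.0),
    "planaria": (0.0, 6.0, 12.0, 24.0, 36.0, 48.0, 72.0),
    "seacucumber": (0.0, 72.0, 168.0, 336.0, 504.0),
}

_PATTERNS = ("EU", "ED", "LU", "LD")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    The planted effect size of 3 log2 units (8-fold), dispersion 0.1 and
    baseline mean 100 match typical bulk regeneration time courses; the
    hit-list mean of 15 matches the observed per-gene annotation-list
    sizes of curated-database alignments.
    """

    seed: int = 0
    species: tuple[str, ...] = tuple(DEFAULT_TIME_GRIDS)
    time_grids: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TIME_GRIDS)
    )
    n_genes_per_species: int = 2000
    n_planted_ortholog_groups: int = 100
    n_common_de: int = 18
    n_accessions: int = 5000
    taxon_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"human": 0.5, "mouse": 0.15, "other": 0.3, "bacteria": 0.05}
    )
    hit_list_size_mean: float = 15.0
    decoy_hit_rate: float = 3.0
    bacterial_hit_rate: float = 0.05
    nb_dispersion: float = 0.1
    baseline_mean: float = 100.0
    planted_patterns: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: {p: (50, 3.0) for p in _PATTERNS}
    )
    n_signature_shared_all: int = 5
    n_signature_shared_two: int = 6
    n_signature_unique: int = 4

    def __post_init__(self) -> None:
        if self.n_planted_ortholog_groups > self.n_genes_per_species:
            raise ValueError("more planted ortholog groups than genes per species")
        if self.n_common_de > self.n_planted_ortholog_groups:
            raise ValueError("n_common_de cannot exceed the number of ortholog groups")
        for p, (n, eff) in self.planted_patterns.items():
            if p not in _PATTERNS:
                raise ValueError(f"unknown pattern '{p}'")
            if n > 0 and eff == 0:
                raise ValueError(f"pattern '{p}' planted with zero effect size")
        for sp in self.species:
            grid = self.time_grids[sp]
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"time grid for '{sp}' not strictly increasing")


@dataclass
class Universe:
    """Synthetic reference-protein accession space."""

    accessions: list[str]
    taxon: dict[str, str]  # accession -> "Eukaryota" | "Bacteria"
    species: dict[str, str]  # accession -> "human" | "mouse" | "other" | "bacteria"

    def by_species(self, species: str) -> list[str]:
        return [a for a in self.accessions if self.species[a] == species]


@dataclass
class TruthTable:
    """Planted ground truth, consistent with the emitted fixtures."""

    ortholog_groups: dict[str, dict[str, str]] = field(default_factory=dict)
    group_accession: dict[str, str] = field(default_factory=dict)
    group_hit_list: dict[str, list[str]] = field(default_factory=dict)
    pattern_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    de_genes: dict[str, list[str]] = field(default_factory=dict)
    common_de_accessions: list[str] = field(default_factory=list)
    signature_shared_all: list[str] = field(default_factory=list)
    consensus_members: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _gene_id(species: str, i: int) -> str:
    return f"{species}_g{i + 1:05d}"


def generate_reference_universe(cfg: GeneratorConfig) -> Universe:
    """Accession universe with deterministic taxon proportions.

    Counts per category are fixed by the configured proportions (largest
    remainder apportionment), so e.g. 50% human over 100 accessions
    yields exactly 50 human-tagged entries; identical seeds give
    identical universes.
    """
    n = cfg.n_accessions
    cats = list(cfg.taxon_proportions)
    raw = np.array([cfg.taxon_proportions[c] for c in cats], dtype=float)
    raw = raw / raw.sum() * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="mergesort")
    for j in range(remainder):
        counts[order[j]] += 1

    accessions: list[str] = []
    taxon: dict[str, str] = {}
    species: dict[str, str] = {}
    i = 0
    for cat, cnt in zip(cats, counts):
        for _ in range(cnt):
            acc = f"ACC{i + 1:06d}"
            accessions.append(acc)
            taxon[acc] = "Bacteria" if cat == "bacteria" else "Eukaryota"
            species[acc] = cat
            i += 1
    return Universe(accessions=accessions, taxon=taxon, species=species)


def generate_hit_tables(
    cfg: GeneratorConfig, universe: Universe
) -> tuple[dict[str, list[HitRecord]], TruthTable]:
    """Per-species hit tables with planted ortholog triplets.

    Each planted group shares one human top accession (high bit score,
    significance on the 1e-30 scale) and one strict-cutoff hit list
    (disjoint between groups) across all species, so best-match and
    list-match co-annotation both have an exact recoverable truth.
    Decoy hits are Poisson-many, strictly lower-scoring than the planted
    top hit, and include a bacterial fraction for the taxon filter.
    """
    rng = np.random.default_rng(cfg.seed)
    n_groups = cfg.n_planted_ortholog_groups
    human = universe.by_species("human")
    if len(human) < n_groups:
        raise ValueError("universe has fewer human accessions than planted groups")
    eukaryote_pool = [a for a in universe.accessions if universe.taxon[a] == "Eukaryota"]
    bacteria_pool = [a for a in universe.accessions if universe.taxon[a] == "Bacteria"]

    top_accs = list(rng.choice(human, size=n_groups, replace=False)) if n_groups else []
    # shared strict hit lists: sampled globally without replacement so
    # lists of different groups are disjoint
    shared_pool = [a for a in eukaryote_pool if a not in set(top_accs)]
    rng.shuffle(shared_pool)
    truth = TruthTable()
    group_lists: list[list[str]] = []
    cursor = 0
    for gi in range(n_groups):
        extra = max(0, int(rng.poisson(max(cfg.hit_list_size_mean - 1, 0))))
        extra = min(extra, len(shared_pool) - cursor)
        group_lists.append(shared_pool[cursor : cursor + extra])
        cursor += extra

    tables: dict[str, list[HitRecord]] = {}
    for sp in cfg.species:
        records: list[HitRecord] = []
        for i in range(cfg.n_genes_per_species):
            gid = _gene_id(sp, i)
            if i < n_groups:
                top = top_accs[i]
                top_score = float(rng.uniform(400, 600))
                top_sig = 10.0 ** (-float(rng.uniform(25, 40)))
                records.append(
                    HitRecord(
                        query_id=gid,
                        subject_acc=top,
                        subject_taxon="Eukaryota",
                        subject_species="human",
                        bit_score=top_score,
                        sig_value=top_sig,
                    )
                )
                for acc in group_lists[i]:
                    records.append(
                        HitRecord(
                            query_id=gid,
                            subject_acc=acc,
                            subject_taxon=universe.taxon[acc],
                            subject_species=universe.species[acc],
                            bit_score=float(rng.uniform(100, top_score - 1)),
                            sig_value=10.0 ** (-float(rng.uniform(15, 25))),
                        )
                    )
                ceiling = top_score - 1
            else:
                ceiling = 300.0
            n_decoys = int(rng.poisson(cfg.decoy_hit_rate))
            for _ in range(n_decoys):
                acc = eukaryote_pool[int(rng.integers(len(eukaryote_pool)))]
                records.append(
                    HitRecord(
                        query_id=gid,
                        subject_acc=acc,
                        subject_taxon=universe.taxon[acc],
                        subject_species=universe.species[acc],
                        bit_score=float(rng.uniform(50, ceiling)),
                        sig_value=10.0 ** (-float(rng.uniform(2, 20))),
                    )
                )
            if bacteria_pool and rng.random() < cfg.bacterial_hit_rate:
                acc = bacteria_pool[int(rng.integers(len(bacteria_pool)))]
                records.append(
                    HitRecord(
                        query_id=gid,
                        subject_acc=acc,
                        subject_taxon="Bacteria",
                        subject_species="bacteria",
                        bit_score=float(rng.uniform(50, 600)),
                        sig_value=10.0 ** (-float(rng.uniform(2, 30))),
                    )
                )
        tables[sp] = records

    for gi in range(n_groups):
        gname = f"group{gi + 1:04d}"
        truth.ortholog_groups[gname] = {sp: _gene_id(sp, gi) for sp in cfg.species}
        truth.group_accession[gname] = top_accs[gi]
        truth.group_hit_list[gname] = [top_accs[gi], *group_lists[gi]]
    return tables, truth


def _phase_indices(grid: Sequence[float]) -> tuple[list[int], int]:
    """Early indices and recovery index of a grid (mirrors phase defaults)."""
    n_nonbase = len(grid) - 1
    early = [1] if n_nonbase < 3 else [1, 2]
    recovery = len(grid) - 1
    return early, recovery


def generate_timecourse_counts(
    cfg: GeneratorConfig, truth: TruthTable | None = None
) -> tuple[dict[str, CountMatrix], TruthTable]:
    """NB count time courses with planted temporal patterns.

    Null genes draw NB(mean = baseline_mean, dispersion phi) at every
    time point.  EU/ED genes have their mean multiplied by 2^(+/-effect)
    at the early indices only, returning to baseline afterwards; LU/LD
    genes sustain the shift from the first non-baseline point onward.
    The first ``n_common_de`` ortholog-planted genes carry a pattern in
    every species (cycling EU/ED/LU/LD); dedicated pattern genes follow
    the ortholog block so planted-ortholog and planted-pattern truths
    stay separable.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    truth = truth if truth is not None else TruthTable()
    matrices: dict[str, CountMatrix] = {}
    phi = cfg.nb_dispersion

    for sp in cfg.species:
        grid = np.array(cfg.time_grids[sp], dtype=float)
        n_t = grid.size
        early, _recovery = _phase_indices(grid)
        n = cfg.n_genes_per_species
        mu = np.full((n, n_t), cfg.baseline_mean, dtype=float)
        labels: dict[str, str] = {}

        def plant(row: int, pattern: str, effect: float) -> None:
            factor = 2.0 ** (effect if pattern in ("EU", "LU") else -effect)
            if pattern in ("EU", "ED"):
                mu[row, early] *= factor
            else:
                mu[row, 1:] *= factor
            labels[_gene_id(sp, row)] = pattern

        for j in range(cfg.n_common_de):
            plant(j, _PATTERNS[j % 4], cfg.planted_patterns[_PATTERNS[j % 4]][1])
        row = cfg.n_planted_ortholog_groups
        for pattern in _PATTERNS:
            n_plant, effect = cfg.planted_patterns.get(pattern, (0, 0.0))
            for _ in range(n_plant):
                if row >= n:
                    raise ValueError("not enough genes to host the planted patterns")
                plant(row, pattern, effect)
                row += 1

        if phi > 0:
            r = 1.0 / phi
            counts = rng.negative_binomial(r, r / (r + mu))
        else:
            counts = rng.poisson(mu)
        matrices[sp] = CountMatrix(
            species=sp,
            gene_ids=[_gene_id(sp, i) for i in range(n)],
            time_points_h=grid,
            counts=counts.astype(np.int64),
        )
        truth.pattern_labels[sp] = labels
        truth.de_genes[sp] = sorted(labels)

    truth.common_de_accessions = [
        truth.group_accession[g]
        for g in sorted(truth.group_accession)[: cfg.n_common_de]
        if g in truth.group_accession
    ]
    return matrices, truth


def generate_signature_fixture(
    cfg: GeneratorConfig, universe: Universe, truth: TruthTable | None = None
) -> tuple[dict[str, list[str]], dict[str, dict[str, list[str]]], TruthTable]:
    """Signature lists with controlled overlap plus a consensus fixture.

    Returns ``(source_lists, per_dataset_de_lists, truth)``.  Three
    source lists share exactly ``n_signature_shared_all`` accessions,
    pairs share ``n_signature_shared_two`` more, and each list carries
    unique members — so shared-membership truths are exact.  The
    consensus fixture plants accessions meeting the 2-of-4 murine /
    3-of-8 human support rule alongside under-supported decoys.
    Signature members are drawn from the planted ortholog top
    accessions, so they are present in every synthetic species.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    truth = truth if truth is not None else TruthTable()
    n_all = cfg.n_signature_shared_all
    n_two = cfg.n_signature_shared_two
    n_uni = cfg.n_signature_unique

    pool = [truth.group_accession[g] for g in sorted(truth.group_accession)]
    # top up from unplanted human accessions when few ortholog groups exist
    planted = set(pool)
    pool += [a for a in universe.by_species("human") if a not in planted]
    needed = n_all + 3 * n_two + 3 * n_uni
    if len(pool) < needed:
        raise ValueError(f"accession pool too small for signature fixture ({len(pool)} < {needed})")
    picks = list(pool[:needed])
    shared_all = picks[:n_all]
    rest = picks[n_all:]
    pair_ab, pair_bc, pair_ac = (
        rest[:n_two],
        rest[n_two : 2 * n_two],
        rest[2 * n_two : 3 * n_two],
    )
    uniq = rest[3 * n_two :]
    uni_a, uni_b, uni_c = uniq[:n_uni], uniq[n_uni : 2 * n_uni], uniq[2 * n_uni :]
    source_lists = {
        "list_a": shared_all + pair_ab + pair_ac + uni_a,
        "list_b": shared_all + pair_ab + pair_bc + uni_b,
        "list_c": shared_all + pair_bc + pair_ac + uni_c,
    }
    truth.signature_shared_all = list(shared_all)

    # consensus fixture: murine group of 4 datasets (support >= 2) and
    # human group of 8 (support >= 3), with known pass/fail members
    consensus = [a for a in shared_all]
    decoys = pair_ab[: max(1, len(pair_ab) // 2)]
    murine = {f"mur{d + 1}": [] for d in range(4)}
    human_ds = {f"hum{d + 1}": [] for d in range(8)}
    for a in consensus:
        for ds in rng.choice(sorted(murine), size=2, replace=False):
            murine[ds].append(a)
        for ds in rng.choice(sorted(human_ds), size=3, replace=False):
            human_ds[ds].append(a)
    for a in decoys:
        murine[sorted(murine)[int(rng.integers(4))]].append(a)
        for ds in rng.choice(sorted(human_ds), size=2, replace=False):
            human_ds[ds].append(a)
    per_dataset = {"murine": murine, "human": human_ds}
    truth.consensus_members = sorted(a.upper() for a in consensus)
    return source_lists, per_dataset, truth


def generate_reciprocal_fixture(
    n_pairs: int = 40, n_decoys: int = 100, seed: int = 0
) -> tuple[list[HitRecord], list[HitRecord], set[tuple[str, str]]]:
    """Two directed hit tables with planted reciprocal best pairs.

    ``n_pairs`` gene pairs are mutual top hits passing coverage/identity
    thresholds (0.4 / 0.6); ``n_decoys`` extra hits exist in one
    direction only.  Returns the two tables and the planted pair set.
    """
    rng = np.random.default_rng(seed)
    ab: list[HitRecord] = []
    ba: list[HitRecord] = []
    planted: set[tuple[str, str]] = set()
    for i in range(n_pairs):
        ga, gb = f"spA_g{i:04d}", f"spB_g{i:04d}"
        planted.add((ga, gb))
        for table, q, s in ((ab, ga, gb), (ba, gb, ga)):
            table.append(
                HitRecord(
                    query_id=q,
                    subject_acc=s,
                    subject_taxon="Eukaryota",
                    subject_species="other",
                    bit_score=float(rng.uniform(300, 500)),
                    sig_value=1e-40,
                    query_coverage=float(rng.uniform(0.5, 0.9)),
                    identity_frac=float(rng.uniform(0.65, 0.95)),
                )
            )
    for j in range(n_decoys):
        ga, gb = f"spA_gd{j:04d}", f"spB_gd{j:04d}"
        ab.append(
            HitRecord(
                query_id=ga,
                subject_acc=gb,
                subject_taxon="Eukaryota",
                subject_species="other",
                bit_score=float(rng.uniform(100, 290)),
                sig_value=1e-10,
                query_coverage=float(rng.uniform(0.5, 0.9)),
                identity_frac=float(rng.uniform(0.65, 0.95)),
            )
        )
    return ab, ba, planted


def hit_table_frame(records: Sequence[HitRecord]) -> pd.DataFrame:
    """Hit records as the on-disk 6-column tab-separated layout."""
    return pd.DataFrame(
        {
            "query_id": [h.query_id for h in records],
            "subject_acc": [h.subject_acc for h in records],
            "subject_taxon": [h.subject_taxon for h in records],
            "subject_species": [h.subject_species for h in records],
            "bit_score": [h.bit_score for h in records],
            "sig_value": [h.sig_value for h in records],
        }
    )


def write_fixture(cfg: GeneratorConfig, out_dir: str | Path) -> TruthTable:
    """Write a complete fixture directory: hit tables, count matrices,
    signature lists and the truth table (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    universe = generate_reference_universe(cfg)
    tables, truth = generate_hit_tables(cfg, universe)
    matrices, truth = generate_timecourse_counts(cfg, truth)
    source_lists, per_dataset, truth = generate_signature_fixture(cfg, universe, truth)

    for sp, records in tables.items():
        hit_table_frame(records).to_csv(
            out / f"hits_{sp}.tsv", sep="\t", index=False, header=False,
            lineterminator="\n", float_format="%.10g",
        )
    for sp, cm in matrices.items():
        cm.write(out / f"counts_{sp}.tsv")
    for name, accs in source_lists.items():
        (out / f"signature_{name}.txt").write_text("\n".join(accs) + "\n")
    for group, datasets in per_dataset.items():
        for ds, accs in datasets.items():
            (out / f"de_{group}_{ds}.txt").write_text(
                ("\n".join(accs) + "\n") if accs else "# empty\n"
            )
    (out / "truth.json").write_text(truth.to_json() + "\n")
    return truth
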