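"""Shared fixtures: a small generated study directory plus its run config."""

from pathlib import Path

import pytest
import yaml

from xregen.synthetic_data import GeneratorConfig, write_fixture

SMALL_STUDY = dict(
    n_genes_per_species=150,
    n_planted_ortholog_groups=30,
    n_common_de=6,
    n_accessions=1500,
    planted_patterns={p: (8, 3.0) for p in ("EU", "ED", "LU", "LD")},
)


def make_run_config(fixture_dir: Path, out_dir: str = "out", **overrides) -> Path:
    """Write a YAML run config pointing at a generated fixture directory."""
    species = {}
    for p in sorted(fixture_dir.glob("hits_*.tsv")):
        name = p.stem.removeprefix("hits_")
        species[name] = {"hits": p.name, "counts": f"counts_{name}.tsv"}
    if "seacucumber" in species:
        species["seacucumber"]["early_indices"] = [1]
    cfg = {
        "species": species,
        "signatures": {
            "lists": {
                p.stem.removeprefix("signature_"): p.name
                for p in sorted(fixture_dir.glob("signature_*.txt"))
            }
        },
        "out_dir": out_dir,
        "seed": 0,
    }
    cfg.update(overrides)
    path = fixture_dir / "run.yaml"
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(GeneratorConfig(seed=1, **SMALL_STUDY), d)
    return d
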