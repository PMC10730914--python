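"""Shared fixtures: small simulated clades and one full preset pipeline run."""

from __future__ import annotations

import pytest

from tropanevo.pathway import load_default_pathway
from tropanevo.presets import (FIG4_REFERENCES, FIG4_TREE, fig4_config,
                               fig4_key_site_column)
from tropanevo.simulate import SimConfig, generate_dataset, write_dataset
from tropanevo.workspace import PipelineConfig, PipelineRun, load_workspace

SMALL_TREE = "((Aaa:10,Bbb:10)AB:6,(Ccc:12,Ddd:12)CD:4)ROOT;"


@pytest.fixture(scope="session")
def default_model():
    return load_default_pathway()


def small_config(seed: int = 11, **overrides) -> SimConfig:
    base = dict(
        seed=seed,
        n_chromosomes=1,
        n_background_genes_per_chrom=30,
        loss_rate=0.0,
        pseudogenization_rate=0.0,
        translocation_rate=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """A quiet four-leaf clade: no gene-level events, sequences only drift."""
    return generate_dataset(SMALL_TREE, small_config())


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory, small_sim):
    """Full pipeline on the small clade (exhaustive alignment, no prescreen)."""
    root = tmp_path_factory.mktemp("small_ws")
    write_dataset(small_sim, root)
    cfg = PipelineConfig(references=["Aaa"], ks_species=["Aaa"])
    cfg.align.prefilter = "edlib"
    ws = load_workspace(root / "manifest.yaml", cfg)
    run = PipelineRun(ws, root / "run")
    run.run()
    return small_sim, ws, run


@pytest.fixture(scope="session")
def fig4_run(tmp_path_factory):
    """The full fig4-like study condition: simulate, write, run every stage."""
    root = tmp_path_factory.mktemp("fig4_ws")
    result = generate_dataset(FIG4_TREE, fig4_config(seed=7))
    write_dataset(result, root, key_sites=fig4_key_site_column())
    cfg = PipelineConfig(
        references=list(FIG4_REFERENCES),
        depth_pairs=[("Hnig", "Atan")],
        ks_species=["Atan"],
    )
    ws = load_workspace(root / "manifest.yaml", cfg)
    run = PipelineRun(ws, root / "run")
    run.run()
    return result, ws, run
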