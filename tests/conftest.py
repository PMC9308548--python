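"""Shared fixtures: small synthetic datasets and one full pipeline run."""

from __future__ import annotations

import pytest

from methego import PipelineConfig, run_pipeline
from methego.simulate import SimulationDesign, simulate_dataset, write_dataset


@pytest.fixture(scope="session")
def small_design() -> SimulationDesign:
    """A desk-scale design whose differential genes support the module/sets."""
    return SimulationDesign(
        n_probes=4000, n_genes=400, n_case=15, n_control=9,
        frac_diff=0.15, module_size=10, seed=1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """(beta, annot, edges, gene_sets, truth) for the small design."""
    return simulate_dataset(small_design)


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def fixture_design() -> SimulationDesign:
    """Study-shaped fixture (29 case / 9 control) scaled down for speed."""
    return SimulationDesign(
        n_probes=3000, n_genes=300, n_case=29, n_control=9,
        frac_diff=0.15, module_size=10, seed=11,
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, fixture_design):
    """One end-to-end pipeline run on the study-shaped fixture."""
    root = tmp_path_factory.mktemp("pipeline")
    paths = write_dataset(fixture_design, root / "data")
    config = PipelineConfig(rng_seed=fixture_design.seed)
    manifest = run_pipeline(config, paths["beta"], paths["annot"], paths["groups"],
                            paths["edges"], paths["gmt"], root / "out")
    return {"manifest": manifest, "paths": paths, "out": root / "out",
            "config": config, "design": fixture_design}
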