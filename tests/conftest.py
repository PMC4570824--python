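"""Shared fixtures: a scaled-down synthetic study for module tests and the
default-size study (session-scoped) for the end-to-end recovery checks."""

import dataclasses

import pytest

from mirdeg.mirna_discovery import DiscoveryConfig
from mirdeg.pipeline import RunConfig, run_all
from mirdeg.synthetic_data import SimConfig, build_truth


def small_sim_config(**overrides) -> SimConfig:
    """A fast study: fewer loci and a narrower fold window."""
    base = dict(
        n_precursors=4, n_known=5, n_transcripts=12, n_chroms=2,
        intergenic_len=1500, n_targets_known=4, n_targets_novel=3,
        n_hotspots=40,
        discovery=DiscoveryConfig(flank=70),
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return build_truth(small_cfg, 7)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default study conditions (seed 1)."""
    out = tmp_path_factory.mktemp("default_run")
    return run_all(RunConfig(out_dir=str(out), seed=1))


def replace_cfg(cfg: SimConfig, **overrides) -> SimConfig:
    return dataclasses.replace(cfg, **overrides)
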