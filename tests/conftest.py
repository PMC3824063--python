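"""Shared fixtures: the default synthetic study is generated once per
session and its (expensive) two-condition pipeline run is shared by the
synthetic-data, pipeline and end-to-end recovery tests."""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import settings as hypothesis_settings

from mirnforge.features import ConservationTrack

hypothesis_settings.register_profile("fixed", derandomize=True, deadline=None)
hypothesis_settings.load_profile("fixed")
from mirnforge.pipeline import PairResult, PipelineConfig, run_condition_pair
from mirnforge.synth import (
    SyntheticDataset,
    SyntheticSpec,
    make_conservation_track,
    plant_hairpins,
    simulate_reads,
)

E2E_SEED = 1


@dataclass
class Study:
    dataset: SyntheticDataset
    reads: dict
    counts: object
    conservation: ConservationTrack
    pair: PairResult


@pytest.fixture(scope="session")
def dataset() -> SyntheticDataset:
    return plant_hairpins(SyntheticSpec(seed=E2E_SEED))


@pytest.fixture(scope="session")
def study(dataset) -> Study:
    reads, counts = simulate_reads(dataset)
    cons = make_conservation_track(dataset)
    pair = run_condition_pair(
        reads,
        dataset.ordered_tiers(),
        dataset.genome,
        dataset.truth.known_mature_loci(),
        cons,
        PipelineConfig(seed=E2E_SEED),
    )
    return Study(dataset, reads, counts, cons, pair)


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    """A down-scaled study for tests that need their own pipeline runs."""
    return SyntheticSpec(
        genome_length=50_000,
        n_known_mirnas=5,
        n_novel_mirnas=4,
        n_decoy_rnas=8,
        reads_per_sample=8_000,
        seed=7,
    )
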