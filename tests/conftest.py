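"""Shared fixtures: a small synthetic experiment run once per session."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import spotquant as sq
from spotquant.config import PipelineConfig
from spotquant.pipeline import layout_from_config, run_pipeline


@dataclass
class SimRun:
    """One simulated experiment plus its pipeline output."""

    config: PipelineConfig
    design: sq.ArrayDesign
    transcriptome: sq.SyntheticTranscriptome
    profiles: sq.SpotProfiles
    fwd: str
    rev: str
    truth: sq.GroundTruth
    result: "sq.PipelineResult"


def _simulate_and_run(tmpdir, seed: int, **sim_kwargs) -> SimRun:
    cfg = PipelineConfig()
    design = sq.make_array_design(n_spots=20, n_cols=5, seed=seed)
    tx = sq.make_transcriptome(n_genes=30, seed=seed + 1)
    profiles = sq.make_spot_profiles(
        design, tx, baseline_mean=5.0, region_size=5, seed=seed + 2
    )
    fwd, rev, truth = sq.simulate_reads(
        profiles,
        tx,
        layout_from_config(cfg),
        tmpdir / "r1.fastq",
        tmpdir / "r2.fastq",
        seed=seed + 3,
        **sim_kwargs,
    )
    result = run_pipeline(fwd, rev, design, tx, config=cfg, keep_assignments=True)
    return SimRun(cfg, design, tx, profiles, str(fwd), str(rev), truth, result)


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory) -> SimRun:
    """Small noise-free experiment: every read should trace to its molecule."""
    return _simulate_and_run(
        tmp_path_factory.mktemp("clean"),
        seed=10,
        dup_mean=3.0,
        error_rate=0.0,
        tail_lowq_prob=0.0,
        rrna_fraction=0.0,
        noise_fraction=0.0,
    )


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory) -> SimRun:
    """Small experiment with the generator's realistic noise defaults."""
    return _simulate_and_run(tmp_path_factory.mktemp("noisy"), seed=20)
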