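from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from sdmod.io import LocusSequence
from sdmod.pipeline import PipelineConfig, RunReport, run_all
from sdmod.synth import SyntheticConfig, TruthTable, write_scenario


@dataclass
class Scenario:
    cfg: SyntheticConfig
    a_like: LocusSequence
    b_like: LocusSequence
    truth: TruthTable
    b_fasta: Path
    a_fasta: Path
    reads_fasta: Path
    pipeline_cfg: PipelineConfig
    report: RunReport


@pytest.fixture(scope="session")
def scenario(tmp_path_factory) -> Scenario:
    """The default synthetic study scenario, run end to end once per session."""
    root = tmp_path_factory.mktemp("scenario")
    cfg = SyntheticConfig(seed=1)
    paths = write_scenario(cfg, root)
    pcfg = PipelineConfig(
        b_fasta=str(paths["b_fasta"]),
        a_fasta=str(paths["a_fasta"]),
        reads=str(paths["reads_fasta"]),
        outdir=str(root / "pipeline"),
        seed=cfg.seed,
    )
    report = run_all(pcfg)
    return Scenario(
        cfg,
        paths["a_like"],
        paths["b_like"],
        paths["truth"],
        paths["b_fasta"],
        paths["a_fasta"],
        paths["reads_fasta"],
        pcfg,
        report,
    )
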