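"""Shared fixtures: hand-built toy genes and seeded synthetic studies."""

from dataclasses import dataclass, field

import numpy as np
import pytest

from exitron_scan import gio, synthio


@dataclass
class Study:
    config: synthio.SynthConfig
    genome: gio.GenomeSequence
    models: list
    truth: synthio.TruthSet
    junctions: dict = field(default_factory=dict)
    coverage: dict = field(default_factory=dict)

    @property
    def samples(self):
        return sorted(self.config.psi_map)


def make_study(config: synthio.SynthConfig) -> Study:
    genome, models, truth = synthio.generate_genome(config)
    study = Study(config=config, genome=genome, models=models, truth=truth)
    for s in study.samples:
        j, c = synthio.simulate_evidence(truth, models, genome, config.depth,
                                         s, config.seed)
        study.junctions[s] = j
        study.coverage[s] = c
    return study


@pytest.fixture(scope="session")
def small_study() -> Study:
    """40 genes, half with a planted exitron, two samples, mid-range PSI."""
    cfg = synthio.SynthConfig(
        n_genes=40, exitron_fraction=0.5, depth=100,
        psi_map={"a": (20.0, 80.0), "b": (20.0, 80.0)}, seed=3)
    return make_study(cfg)


@pytest.fixture(scope="session")
def deep_study() -> Study:
    """Every gene hosts an exitron; deep evidence for PSI recovery checks."""
    cfg = synthio.SynthConfig(
        n_genes=60, exitron_fraction=1.0, depth=500,
        psi_map={"a": (20.0, 80.0)}, seed=9)
    return make_study(cfg)


def _toy_sequence() -> str:
    """400 nt with a 2-exon gene: exon [10,100) + intron [100,160) + exon
    [160,310); an exitron-like GT..AG interval sits at [200,260)."""
    seq = list("A" * 400)
    seq[10:13] = "ATG"
    seq[100:102] = "GT"
    seq[158:160] = "AG"
    seq[200:202] = "GT"
    seq[258:260] = "AG"
    seq[307:310] = "TAA"
    return "".join(seq)


@pytest.fixture(scope="session")
def toy_genome() -> gio.GenomeSequence:
    return gio.GenomeSequence({"t": _toy_sequence()})


@pytest.fixture(scope="session")
def toy_model() -> gio.TranscriptModel:
    return gio.TranscriptModel(
        gene_id="TOY1", transcript_id="TOY1.1", contig="t", strand="+",
        exons=((10, 100), (160, 310)), cds=((10, 100), (160, 310)))
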