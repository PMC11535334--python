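"""Shared fixtures: hand-written annotation/mapping fixtures and
session-scoped synthetic screens."""
from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from coauxseq import SimConfig
from coauxseq import simulate as sim

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


TOY_GFF = """##gff-version 3
g1\ttoy\tgene\t101\t400\t.\t+\t.\tID=geneA
g1\ttoy\tCDS\t101\t400\t.\t+\t0\tID=cds-geneA;Parent=geneA
g1\ttoy\tgene\t600\t1199\t.\t-\t.\tID=geneB
g1\ttoy\tCDS\t600\t1199\t.\t-\t0\tID=cds-geneB;Parent=geneB
g1\ttoy\tgene\t1500\t2099\t.\t+\t.\tID=geneC
g1\ttoy\tCDS\t1500\t2099\t.\t+\t0\tID=cds-geneC;Parent=geneC
"""


@pytest.fixture
def toy_gff(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF)
    return path


def _screen(config: SimConfig, n_complementing: int, n_selected: int):
    _, annotation = sim.simulate_genome(config)
    comp = sim.default_complementing_genes(annotation, n_complementing, config.seed)
    config = dataclasses.replace(config, complementing_genes=comp)
    genome, annotation, mapping, truth, counts = sim.simulate_screen(
        config, n_selected=n_selected
    )
    return {
        "config": config,
        "genome": genome,
        "annotation": annotation,
        "mapping": mapping,
        "truth": truth,
        "counts": counts,
    }


@pytest.fixture(scope="session")
def screen():
    """A default-condition screen: 2 complementing genes, two inducer
    levels, stochastic winner draws at 0.66/0.35."""
    cfg = SimConfig(
        seed=7, genome_length=400_000, n_genes=60, n_fragments=2000,
        depth_t0=200_000, depth_sel=200_000,
    )
    return _screen(cfg, n_complementing=2, n_selected=2)


@pytest.fixture(scope="session")
def exact_screen():
    """Noise-free selection: every sense carrier detected at t0 wins,
    antisense never, no background mass, no read errors."""
    cfg = SimConfig(
        seed=3, genome_length=400_000, n_genes=60, n_fragments=2000,
        depth_t0=200_000, depth_sel=200_000,
        p_sense=1.0, p_antisense=0.0, background_mass=0.0, read_error_rate=0.0,
    )
    return _screen(cfg, n_complementing=2, n_selected=2)
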