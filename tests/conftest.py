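"""Shared fixtures: small genomes and panels generated at test time."""

from __future__ import annotations

import pytest

from hrdscar.genome_model import GenomeBuild, grch37, toy_genome
from hrdscar.simulator import synthetic_panel


@pytest.fixture(scope="session")
def toy() -> GenomeBuild:
    """Three 100-Mb metacentric chromosomes; centromere at the middle 3%."""
    return toy_genome()


@pytest.fixture(scope="session")
def autosomes() -> GenomeBuild:
    """GRCh37 autosomes (packaged lengths + centromere intervals)."""
    return grch37(include_sex=False)


@pytest.fixture(scope="session")
def toy_panel(toy):
    """~50-kb-spaced synthetic SNP panel on the toy genome (6000 SNPs)."""
    return synthetic_panel(toy, spacing=50_000, seed=42)


@pytest.fixture(scope="session")
def coarse_panel(autosomes):
    """100-kb-spaced panel on GRCh37 autosomes used by the experiments."""
    return synthetic_panel(autosomes, spacing=100_000, seed=42)


@pytest.fixture
def simple_genome() -> GenomeBuild:
    """One 150-Mb chromosome with centromere [60, 63) Mb, for worked examples."""
    return GenomeBuild(
        [("chr1", 150_000_000)],
        {"chr1": (60_000_000, 63_000_000)},
        name="example",
    )
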