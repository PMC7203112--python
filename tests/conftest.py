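import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from coopbind import ArrangementSpec, Layout, MotifPattern
from coopbind import synthetic_data as sd

TGAA = MotifPattern("TGAA", "TGAA")
TAAT = MotifPattern("TAAT", "TAAT")
GBOX = MotifPattern("G-Box", "TCACGTGA")


@pytest.fixture
def tgaa():
    return TGAA


@pytest.fixture
def direct_2x():
    return ArrangementSpec(TGAA, Layout.DIRECT_REPEAT, copies=2, name="direct")


@pytest.fixture
def arrangement_panel():
    """The four orientation/spacing classes with their measured affinities (µM)."""
    specs = [
        ArrangementSpec(TGAA, Layout.DIRECT_REPEAT, copies=2, name="direct"),
        ArrangementSpec(TGAA, Layout.INVERTED_TAIL_TO_TAIL, copies=2, name="inverted"),
        ArrangementSpec(TGAA, Layout.EVERTED_HEAD_TO_HEAD, copies=2, name="everted"),
        ArrangementSpec(TGAA, Layout.DIRECT_REPEAT, copies=2, spacer_nt=1, name="spaced1"),
    ]
    kds = {"direct": 0.27, "inverted": 1.90, "everted": 3.17, "spaced1": 2.21}
    return specs, kds


@pytest.fixture
def small_synthetic(arrangement_panel):
    """A small planted genome with reads, for end-to-end tests."""
    specs, kds = arrangement_panel
    plants = tuple(sd.PlantSpec(s, 25, kds[s.name]) for s in specs)
    gspec = sd.SyntheticGenomeSpec(
        n_chroms=2, chrom_length=20_000, plants=plants, min_plant_spacing=100, seed=42
    )
    genome, truth = sd.generate_genome(gspec)
    reads = sd.simulate_reads(
        {c: len(s) for c, s in genome.items()}, truth, sd.ReadSimSpec(seed=43)
    )
    return genome, truth, reads, specs


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
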