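import numpy as np
import pytest

from asmapper.model import Gene, ProfileTrack, Tss
from asmapper.simulate import SimConfig, simulate


@pytest.fixture
def plus_gene():
    """A + strand gene [1000, 2000) used by the classification examples."""
    return Gene("VNG_RS00005", "chr", 1000, 2000, "+")


@pytest.fixture
def minus_gene():
    return Gene("VNG_RS00010", "chr", 1000, 2000, "-")


@pytest.fixture(scope="session")
def clean_dataset():
    """Saturating-depth, zero-noise synthetic dataset (shared; read-only)."""
    return simulate(SimConfig(noise_rate=0.0), seed=20, species_b=True)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-condition synthetic dataset (background noise present)."""
    return simulate(SimConfig(), seed=21, species_b=True)


def make_track(values, strand="+", kind="coverage", lib="lib1", replicon="chr"):
    return ProfileTrack(replicon=replicon, strand=strand, library_id=lib,
                        kind=kind, values=np.asarray(values, dtype=np.int64))


def make_tss(position, strand="+", tss_id="aTSS_1", replicon="chr",
             tss_class="antisense", cognates=()):
    return Tss(id=tss_id, replicon=replicon, position=position, strand=strand,
               tss_class=tss_class, cognate_genes=list(cognates))
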