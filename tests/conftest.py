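import numpy as np
import pytest

from tagscan import FixtureParams, make_fixture
from tagscan.cne_builder import ConservedElement


def make_cne(sequence, mask=None, cne_id="cne_x", chrom="chr1", start=0):
    """Bare ConservedElement from a sequence and optional bool mask."""
    seq = sequence.upper()
    if mask is None:
        mask = np.ones(len(seq), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    return ConservedElement(cne_id, chrom, start, start + len(seq), seq, mask)


def random_cne(rng, length, cne_id="cne_r", conservation=0.9, start=0):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    mask = rng.random(length) < conservation
    return make_cne(seq, mask, cne_id=cne_id, start=start)


SMALL_PARAMS = dict(
    n_genes=60,
    tissue_sizes={"anterior_ns": 15, "posterior_ns": 15, "muscle": 30},
    planted_motif="GATTA",
    planted_tissue="anterior_ns",
    enrichment_rate=0.5,
    background_rate=0.05,
    cne_per_gene=2,
    cne_length_mean=143,
    seed=3,
)

# conditions of the planted-recovery study design: three tissues, strong
# but not saturating enrichment over a 5% background
RECOVERY_PARAMS = dict(
    n_genes=300,
    tissue_sizes={"A": 60, "B": 60, "C": 180},
    planted_motif="GATTA",
    planted_tissue="A",
    enrichment_rate=0.4,
    background_rate=0.05,
)


@pytest.fixture(scope="session")
def small_fixture():
    return make_fixture(FixtureParams(**SMALL_PARAMS))


@pytest.fixture(scope="session")
def small_pipeline_inputs(small_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture_files")
    return small_fixture, small_fixture.write(outdir)
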