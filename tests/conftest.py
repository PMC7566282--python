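import numpy as np
import pytest

from tuatlas.core_io import EndCoverageTrack, GeneRecord, GenomeSequence


@pytest.fixture
def toy_genome():
    """60-bp single-replicon genome with a fixed sequence."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    return {"chr": GenomeSequence("chr", seq)}


@pytest.fixture
def toy_genes():
    return [
        GeneRecord("geneA", "chr", 100, 400, "+"),
        GeneRecord("geneB", "chr", 700, 1100, "+"),
        GeneRecord("geneC", "chr", 1300, 1600, "-"),
        GeneRecord("trnaX", "chr", 1700, 1780, "+", feature_class="tRNA"),
    ]


def make_track(lengths, kind="termseq", library_id="lib1", condition="c1",
               replicate="r1"):
    return EndCoverageTrack(library_id, condition, replicate, kind, lengths)


@pytest.fixture
def track_factory():
    return make_track
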