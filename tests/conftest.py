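import numpy as np
import pytest

from repeatclean.genome_io import AnnotationSet, GenomeSequence, IntervalRecord


def make_genome(**contigs) -> GenomeSequence:
    """Build a genome from keyword contigs (order preserved)."""
    return GenomeSequence(dict(contigs))


def whole_contig_targets(genome: GenomeSequence, label: str = "repeat") -> AnnotationSet:
    return AnnotationSet(
        [
            IntervalRecord(name, 0, len(seq), label)
            for name, seq in genome.contigs.items()
        ]
    ).merge()


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
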