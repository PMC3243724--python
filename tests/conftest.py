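import pytest

from pulscape.genome import GeneRecord, GenomeAnnotation
from pulscape.simulate import synth_genome_pair


@pytest.fixture(scope="session")
def planted_pair():
    """Default planted genome pair: 10 shared, 5 inverted, 5 unique per genome."""
    return synth_genome_pair(
        n_puls_shared=10, n_puls_inverted=5, n_puls_unique_each=5,
        n_filler_genes=200, mutation_rate=0.0, seed=1,
    )


def make_annotation(classes, genome_id="g", contig="c", strand=None, gap=100, length=1000):
    """Annotation from a list of functional classes laid out left to right."""
    records = []
    pos = 0
    for i, cls in enumerate(classes):
        s = strand[i] if strand is not None else "+"
        records.append(GeneRecord(f"{genome_id}_{i:03d}", contig, pos, pos + length, s, cls))
        pos += length + gap
    return GenomeAnnotation.from_records(genome_id, records)
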