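import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from intronq.assay_design import DesignParams
from intronq.genome_io import GenomeSequence, Interval, GeneModel
from intronq.simulate import SyntheticGenomeSpec, synthetic_genome_pair


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="genome.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in records))
        return path

    return _write


@pytest.fixture
def write_gff3(tmp_path):
    def _write(lines, name="anno.gff3"):
        path = tmp_path / name
        path.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def default_params():
    return DesignParams()


@pytest.fixture
def three_exon_model():
    # exons of 100 nt separated by 200 nt introns, starting at 50
    exons = (Interval(50, 150), Interval(350, 450), Interval(650, 750))
    return GeneModel(gene_id="g1", chrom="chr1", strand="+", exons=exons)


@pytest.fixture(scope="session")
def genome_pair():
    return synthetic_genome_pair(SyntheticGenomeSpec(seed=7))


@pytest.fixture
def small_genome():
    return GenomeSequence(id="chr1", seq="AACGTTACGTACGGTACC")
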