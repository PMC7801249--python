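import pytest

from backsplice.io import GenomeSequence, GeneModel, Transcript
from backsplice.simulate import (SimConfig, simulate_genome_annotation,
                                 simulate_circ_reads, write_sim_outputs)


def make_sam(tmp_path, lines, name="test.sam",
             sq=(("c1", 5000), ("c2", 5000))):
    """Write a SAM file from header SQ spec + record lines."""
    path = tmp_path / name
    header = ["@HD\tVN:1.6\tSO:unsorted"]
    header += [f"@SQ\tSN:{sn}\tLN:{ln}" for sn, ln in sq]
    path.write_text("\n".join(header + list(lines)) + "\n")
    return str(path)


@pytest.fixture
def toy_genome():
    # two chromosomes with predictable content for coordinate checks
    return GenomeSequence({
        "c1": "ACGT" * 500,          # 2000 bp
        "c2": "AAACCCGGGTTT",
    })


@pytest.fixture
def toy_gene():
    # + strand gene, 3 exons: 101-200, 301-400, 501-700
    return GeneModel(
        gene_id="g1", chrom="c1", strand="+",
        transcripts=[Transcript("t1", [(101, 200), (301, 400), (501, 700)])])


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Error-free small benchmark: 20 circles, 300 BSJ reads on 200 kb."""
    cfg = SimConfig(n_chromosomes=1, chromosome_length=200_000, n_genes=30,
                    n_circrnas=20, n_bsj_reads=300, n_background_reads=200,
                    seed=11)
    genome, genes = simulate_genome_annotation(cfg)
    sim = simulate_circ_reads(genome, genes, cfg)
    out = tmp_path_factory.mktemp("small_sim")
    paths = write_sim_outputs(sim, out)
    return {"config": cfg, "genome": genome, "genes": genes, "sim": sim,
            "paths": paths}
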