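import pytest

from igrscout import synthetic_data as sd
from igrscout.genome_io import Genome, GeneFeature, MotifAlignment, MotifRow
from igrscout.pipeline import run_pipeline

BENCH_SEED = 1


def make_genome(features, length=400, seq=None, circular=False, gid="g1"):
    if seq is None:
        seq = ("ACGT" * (length // 4 + 1))[:length]
    return Genome(genome_id=gid, species_tag=gid, sequence=seq,
                  features=list(features), circular=circular)


def cds(start, end, strand="+", fid=None, product=""):
    return GeneFeature(fid or f"cds_{start}", start, end, strand, "CDS", product)


def rna(start, end, strand="+", fid=None, product="tRNA-Ala"):
    return GeneFeature(fid or f"rna_{start}", start, end, strand, "known_rna", product)


def make_alignment(seqs, motif_id="m", ss=None):
    """Alignment from plain gapped strings; coordinates cover each row."""
    rows = []
    for i, s in enumerate(seqs):
        n = len(s.replace("-", "").replace(".", ""))
        rows.append(MotifRow(igr_id=f"igr{i}", genome_id=f"g{i}", start=0,
                             end=n, strand="+", seq=s))
    return MotifAlignment(motif_id=motif_id, rows=rows, ss_cons=ss)


@pytest.fixture(scope="session")
def bench():
    """One seeded benchmark cohort plus a full pipeline run over it."""
    config = sd.GeneratorConfig()
    genomes, truth = sd.generate_genomes(config, BENCH_SEED)
    result = run_pipeline(genomes)
    return dict(config=config, genomes=genomes, truth=truth, result=result)
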