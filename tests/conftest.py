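import numpy as np
import pandas as pd
import pysam
import pytest

from msrecount import get_enzyme, load_genome
from msrecount.simulate import SimConfig, simulate_experiment, simulate_genome, write_fasta

TOY_SEQ = "TTCCGGAA"  # one MspI site CCGG at [3, 6]


@pytest.fixture(scope="session")
def mspi():
    return get_enzyme("MspI")


@pytest.fixture(scope="session")
def apeki():
    return get_enzyme("ApeKI")


@pytest.fixture()
def toy_genome(tmp_path):
    fa = tmp_path / "toy.fa"
    fa.write_text(f">chr1\n{TOY_SEQ}\n")
    return load_genome(fa)


def make_bam(path, records, contig="chr1", length=8):
    """Write records (qname, flag, pos0, cigar, seq) as a sorted, indexed BAM."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": contig, "LN": length}]}
    )
    segs = []
    for qname, flag, pos0, cigar, seq in records:
        a = pysam.AlignedSegment(header)
        a.query_name = qname
        a.flag = flag
        a.reference_id = 0
        a.reference_start = pos0
        a.mapping_quality = 60
        a.cigarstring = cigar
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        segs.append(a)
    segs.sort(key=lambda r: r.reference_start)
    with pysam.AlignmentFile(path, "wb", header=header) as bf:
        for s in segs:
            bf.write(s)
    pysam.index(str(path))
    return path


@pytest.fixture()
def toy_bam(tmp_path):
    """Two forward reads 5'-anchored at chr1:4 and one reverse read anchored
    at chr1:5, on the TTCCGGAA toy (MspI cut inside CCGG at [3, 6])."""
    records = [
        ("f1", 0, 3, "5M", "CGGAA"),
        ("f2", 0, 3, "5M", "CGGAA"),
        ("r1", 16, 0, "5M", "CGGAA"),  # leftmost 1, span 5 -> 5' end at 5
    ]
    return make_bam(tmp_path / "toy.bam", records)


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory, mspi):
    """A small simulated MRE-seq study: 80 sites, 3 vs 3 samples."""
    d = tmp_path_factory.mktemp("simexp")
    cfg = SimConfig(
        seed=11,
        genome_length=50_000,
        n_target_sites=80,
        groups=(("control", 3), ("treatment", 3)),
        mean_depth=8_000,
        dispersion=0.1,
        dm_fraction=0.1,
        effect_fold=4.0,
        mismap_fraction=0.0,
    )
    seq, occs = simulate_genome(cfg, mspi)
    fa = d / "genome.fa"
    write_fasta(seq, fa)
    bams, truth, meta = simulate_experiment(seq, occs, cfg, mspi, d)
    return {
        "config": cfg,
        "sequence": seq,
        "occurrences": occs,
        "fasta": fa,
        "genome": load_genome(fa),
        "bams": bams,
        "truth": truth,
        "meta": meta,
    }
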