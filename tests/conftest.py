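import pysam
import pytest

from edsplice.simdata import default_fixture_design, simulate_all, sample_names


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """The default mixed-strand fixture, simulated once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    design = default_fixture_design(seed=11)
    layout, truth = simulate_all(design, outdir)
    bams = {s: str(outdir / f"{s}.bam") for s in sample_names(design)}
    return {
        "design": design,
        "layout": layout,
        "truth": truth,
        "dir": outdir,
        "bams": bams,
        "groups": {
            "WT": [s for s in bams if s.startswith("WT")],
            "KO": [s for s in bams if s.startswith("KO")],
        },
        "genotypes": sample_names(design),
    }


@pytest.fixture()
def toy_bam_factory(tmp_path):
    """Write a sorted+indexed BAM from (qname, flag, start, cigartuples, seq)
    tuples on a single toy contig."""

    def make(reads, chrom="chrT", length=100000, name="toy"):
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": length}]}
        tmp = tmp_path / f"{name}.unsorted.bam"
        out = tmp_path / f"{name}.bam"
        with pysam.AlignmentFile(str(tmp), "wb", header=header) as bam:
            for qname, flag, start, cigar, seq in reads:
                a = pysam.AlignedSegment(bam.header)
                a.query_name = qname
                a.flag = flag
                a.reference_id = 0
                a.reference_start = start
                a.mapping_quality = 60
                a.cigartuples = cigar
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                bam.write(a)
        pysam.sort("-o", str(out), str(tmp))
        pysam.index(str(out))
        return str(out)

    return make


@pytest.fixture()
def toy_fasta_factory(tmp_path):
    """Write an indexed FASTA from a {name: sequence} mapping."""

    def make(contigs, name="toy"):
        path = tmp_path / f"{name}.fa"
        with open(path, "w") as fh:
            for cname, seq in contigs.items():
                fh.write(f">{cname}\n{seq}\n")
        pysam.faidx(str(path))
        return str(path)

    return make
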