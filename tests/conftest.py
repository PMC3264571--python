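import numpy as np
import pysam
import pytest

from breedtx.genome import GeneAnnotation, TranscriptModel
from breedtx.simulate import SimulationConfig, simulate_dataset


def make_sam(path, records, contigs):
    """Write a SAM by hand for pileup/compatibility tests.

    ``records`` are dicts with qname, flag, contig, pos (0-based),
    cigar, seq, and optional qual (Phred int or string) / tags.
    """
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for rec in records:
            a = pysam.AlignedSegment()
            a.query_name = rec["qname"]
            a.flag = rec.get("flag", 0)
            a.reference_id = list(contigs).index(rec["contig"])
            a.reference_start = rec["pos"]
            a.mapping_quality = rec.get("mapq", 50)
            a.cigarstring = rec["cigar"]
            a.query_sequence = rec["seq"]
            qual = rec.get("qual", 30)
            if isinstance(qual, int):
                qual = [qual] * len(rec["seq"])
            a.query_qualities = qual
            for tag, val in rec.get("tags", {"NH": 1}).items():
                a.set_tag(tag, val)
            if "pnext" in rec:
                a.next_reference_id = a.reference_id
                a.next_reference_start = rec["pnext"]
            sam.write(a)
    return path


@pytest.fixture()
def sam_factory(tmp_path):
    def _make(records, contigs, name="test.sam"):
        return make_sam(tmp_path / name, records, contigs)

    return _make


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """One modest simulated study reused by read-only tests."""
    out = tmp_path_factory.mktemp("sim")
    cfg = SimulationConfig(seed=11, depth=30)
    return simulate_dataset(cfg, out)


def two_exon_gene(gene_id="g1", contig="chr1", strand="+"):
    """A minimal two-isoform gene (full-length + exon-skipping)."""
    exons = ((100, 200), (300, 400), (500, 600))
    ann = GeneAnnotation(contig_lengths={contig: 1000})
    ann.add(TranscriptModel(f"{gene_id}.t1", gene_id, contig, strand, exons))
    ann.add(
        TranscriptModel(
            f"{gene_id}.t2", gene_id, contig, strand, (exons[0], exons[2])
        )
    )
    return ann
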