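"""Gene models, coordinate arithmetic, and FASTA/GTF I/O.

Internal coordinates are 0-based, half-open, on the genome's forward
strand. GTF is emitted and read as 1-based inclusive (the GTF2.2
dialect: ``exon`` and ``CDS`` features carrying ``gene_id`` and
``transcript_id`` attributes). Transcript coordinates run 5'->3' on the
transcript strand, so position 0 of a minus-strand transcript sits at
the genomic 3'-most exon base.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals, sorted and merged."""
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: an exon chain plus optional CDS intervals.

    ``exons`` and ``cds`` are genomic-sorted half-open intervals; exons
    must be disjoint, and CDS intervals must lie within exons with a
    total length divisible by three.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r}")
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if not (a < b <= c < d):
                raise AnnotationError(
                    f"{self.transcript_id}: exons unsorted or overlapping"
                )
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise AnnotationError(f"{self.transcript_id}: CDS outside exons")
        if self.cds and self.cds_length % 3 != 0:
            raise AnnotationError(
                f"{self.transcript_id}: CDS length {self.cds_length} not a codon multiple"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site.

        On '+' this is the first exon's start; on '-' it is the last
        exon's (exclusive) end, i.e. the 5'-most transcribed base + 1 in
        half-open convention — strict equality of this value is what the
        single-TSS restriction compares.
        """
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def junctions(self) -> frozenset[Interval]:
        """Splice junctions as genomic (donor-side end, acceptor-side start)."""
        return frozenset(self.introns)

    # -- coordinate maps ------------------------------------------------
    def genome_to_transcript(self, gpos: int) -> int:
        """Map a genomic base to its 5'->3' transcript offset.

        Raises ``ValueError`` for intronic/outside positions.
        """
        off = 0
        for s, e in self.exons:
            if s <= gpos < e:
                fwd = off + (gpos - s)
                return fwd if self.strand == "+" else self.length - 1 - fwd
            off += e - s
        raise ValueError(f"{gpos} not exonic in {self.transcript_id}")

    def transcript_to_genome(self, tpos: int) -> int:
        if not 0 <= tpos < self.length:
            raise ValueError(f"transcript position {tpos} out of range")
        fwd = tpos if self.strand == "+" else self.length - 1 - tpos
        for s, e in self.exons:
            if fwd < e - s:
                return s + fwd
            fwd -= e - s
        raise AssertionError("unreachable")

    def transcript_blocks(self, t0: int, t1: int) -> list[Interval]:
        """Genomic blocks (sorted ascending) covered by transcript [t0, t1)."""
        if not 0 <= t0 < t1 <= self.length:
            raise ValueError(f"bad transcript interval [{t0}, {t1})")
        if self.strand == "+":
            f0, f1 = t0, t1
        else:
            f0, f1 = self.length - t1, self.length - t0
        blocks: list[Interval] = []
        off = 0
        for s, e in self.exons:
            lo, hi = max(f0, off), min(f1, off + (e - s))
            if lo < hi:
                blocks.append((s + lo - off, s + hi - off))
            off += e - s
        return blocks

    def spliced_sequence(self, contig_seq: str) -> str:
        """Transcript sequence 5'->3' given the forward contig sequence."""
        seq = "".join(contig_seq[s:e] for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    @property
    def cds_transcript_interval(self) -> Interval:
        """CDS as a [start, end) interval in transcript coordinates."""
        if not self.cds:
            raise ValueError(f"{self.transcript_id} has no CDS")
        tpos = sorted(
            self.genome_to_transcript(p)
            for s, e in self.cds
            for p in (s, e - 1)
        )
        return (tpos[0], tpos[-1] + 1)

    def coding_sequence(self, contig_seq: str) -> str:
        t0, t1 = self.cds_transcript_interval
        return self.spliced_sequence(contig_seq)[t0:t1]


@dataclass
class GeneAnnotation:
    """A set of gene models on shared contigs.

    ``transcripts`` maps transcript id -> :class:`TranscriptModel`;
    ``genes`` maps gene id -> ordered transcript ids. ``contig_lengths``
    may be empty when unknown (e.g. a GTF read without its FASTA).
    """

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes: dict[str, list[str]] = {}
        for tid, tx in self.transcripts.items():
            self.genes.setdefault(tx.gene_id, []).append(tid)

    def add(self, tx: TranscriptModel) -> None:
        self.transcripts[tx.transcript_id] = tx
        self.genes.setdefault(tx.gene_id, []).append(tx.transcript_id)

    def transcripts_of(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[t] for t in self.genes[gene_id]]

    def gene_span(self, gene_id: str) -> tuple[str, int, int]:
        txs = self.transcripts_of(gene_id)
        return (
            txs[0].contig,
            min(t.span[0] for t in txs),
            max(t.span[1] for t in txs),
        )

    def gene_cds_union(self, gene_id: str) -> list[Interval]:
        return _merge_intervals(
            iv for t in self.transcripts_of(gene_id) for iv in t.cds
        )

    def gene_exon_union(self, gene_id: str) -> list[Interval]:
        return _merge_intervals(
            iv for t in self.transcripts_of(gene_id) for iv in t.exons
        )

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    # -- GTF ------------------------------------------------------------
    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for gid in self.genes:
                for tx in self.transcripts_of(gid):
                    attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                    for s, e in tx.exons:
                        fh.write(
                            f"{tx.contig}\tbreedtx\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                        )
                    phase = 0
                    cds = tx.cds if tx.strand == "+" else tuple(reversed(tx.cds))
                    for s, e in cds:
                        fh.write(
                            f"{tx.contig}\tbreedtx\tCDS\t{s + 1}\t{e}\t.\t{tx.strand}\t{phase}\t{attrs}\n"
                        )
                        phase = (3 - ((e - s) - phase) % 3) % 3

    @classmethod
    def read_gtf(cls, path, contig_lengths: Mapping[str, int] | None = None) -> "GeneAnnotation":
        exons: dict[str, list[Interval]] = {}
        cds: dict[str, list[Interval]] = {}
        meta: dict[str, tuple[str, str, str]] = {}
        attr_re = re.compile(r'(\w+) "([^"]*)"')
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise AnnotationError(f"malformed GTF line: {line!r}")
                contig, _src, feat, start, end, _score, strand, _frame, attr = fields[:9]
                if feat not in ("exon", "CDS"):
                    continue
                attrs = dict(attr_re.findall(attr))
                tid = attrs["transcript_id"]
                meta[tid] = (attrs["gene_id"], contig, strand)
                iv = (int(start) - 1, int(end))
                (exons if feat == "exon" else cds).setdefault(tid, []).append(iv)
        ann = cls(contig_lengths=dict(contig_lengths or {}))
        for tid, (gid, contig, strand) in meta.items():
            ann.add(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gid,
                    contig=contig,
                    strand=strand,
                    exons=tuple(sorted(exons.get(tid, []))),
                    cds=tuple(sorted(cds.get(tid, []))),
                )
            )
        return ann


# -- FASTA ---------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
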