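"""Synthetic pooled-RNA-seq study generator with full ground truth.

Emulates the design of a pooled multi-breed leukocyte mRNA-seq
comparison: several breed pools share one reference genome; a handful
of fixed substitutions distinguish breed haplotypes (a controllable
fraction inside coding sequence, including an engineered premature-stop
change that truncates the final five codons of one protein); each pool
additionally segregates within-breed SNPs whose minor-allele fractions
straddle the 10% polymorphism filter; a subset of genes carries two
isoforms sharing a single transcription start site (one skipping an
internal exon) whose relative usage differs between breeds; paired
fragments are sampled from transcripts with configurable sequencing
error and base qualities straddling Q20, and written as spliced SAM
alignments.

Every stochastic choice flows from ``SimulationConfig.seed``; identical
configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .genome import GeneAnnotation, Interval, TranscriptModel, revcomp, write_fasta

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic dataset.

    Defaults are the package's standing test conditions: 20 genes on one
    contig, three breed pools, 30 fixed between-breed substitutions of
    which half are coding, 30 within-breed SNPs per breed with minor
    fractions straddling the 10% filter, half of the genes carrying an
    exon-skipping second isoform at the shared TSS, ~300 bp fragments
    read 75 bp from both ends at 30x fragment coverage.
    """

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (120, 300)
    intron_len: tuple[int, int] = (200, 500)
    two_isoform_frac: float = 0.5
    gene_gap: int = 4000

    n_breeds: int = 3
    breeds: tuple[str, ...] = ()

    n_fixed_diffs: int = 30
    frac_coding_diffs: float = 0.5
    n_within_snps: int = 30
    minor_allele_fracs: tuple[float, ...] = (0.05, 0.08, 0.12, 0.30, 0.45)

    # isoform usage over (full-length, exon-skipping) isoforms
    usage_base: tuple[float, ...] = (0.9, 0.1)
    usage_shifted: tuple[float, ...] = (0.4, 0.6)
    usage_shift_frac: float = 0.5
    isoform_usage: dict | None = None  # optional {breed: {gene: probs}} override

    depth: float = 30.0
    read_len: int = 75
    frag_len: int = 300
    error_rate: float = 0.001
    qual_high: int = 35
    qual_low: int = 15
    error_mode: str = "low_quality"  # or "realistic"
    qual_low_frac: float = 0.1
    tiling: bool = False

    n_intergenic_far: int = 0
    n_intergenic_near: int = 0
    intergenic_len: int = 600
    intergenic_dist_far: int = 1500
    intergenic_dist_near: int = 400

    seed: int = 0

    def __post_init__(self) -> None:
        if not self.breeds:
            self.breeds = tuple(f"breed{i + 1}" for i in range(self.n_breeds))
        self.validate()

    def validate(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigurationError(f"{name}: bad range ({lo}, {hi})")
        if len(self.breeds) != self.n_breeds:
            raise ConfigurationError("breeds list does not match n_breeds")
        if not 0.0 <= self.frac_coding_diffs <= 1.0:
            raise ConfigurationError("frac_coding_diffs must be in [0, 1]")
        if not 0.0 <= self.two_isoform_frac <= 1.0:
            raise ConfigurationError("two_isoform_frac must be in [0, 1]")
        if self.depth <= 0:
            raise ConfigurationError("depth must be positive")
        if self.read_len > self.frag_len:
            raise ConfigurationError("read_len must not exceed frag_len")
        for u in (self.usage_base, self.usage_shifted):
            if abs(sum(u) - 1.0) > 1e-9:
                raise ConfigurationError(f"usage vector {u} does not sum to 1")
        for f in self.minor_allele_fracs:
            if not 0.0 < f <= 0.5:
                raise ConfigurationError(f"minor allele fraction {f} outside (0, 0.5]")
        if not (self.qual_high >= 20 > self.qual_low):
            raise ConfigurationError("expect qual_high >= 20 > qual_low")
        if self.error_mode not in ("low_quality", "realistic"):
            raise ConfigurationError(f"unknown error_mode {self.error_mode!r}")
        n_intergenic = self.n_intergenic_far + self.n_intergenic_near
        if n_intergenic > max(0, self.n_genes - 1):
            raise ConfigurationError("too many intergenic transcripts for the gene gaps")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("exons_per_gene", "exon_len", "intron_len", "breeds",
                    "minor_allele_fracs", "usage_base", "usage_shifted"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        for key, val in raw.items():
            if isinstance(val, tuple):
                raw[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass(frozen=True)
class VariantTruth:
    """Ground truth for one spiked site (0-based position)."""

    contig: str
    position: int
    kind: str  # fixed_between | snp_within
    breed_alleles: dict  # fixed: breed -> base; snp: breed -> (major, minor, minor_frac)
    region: str  # CDS | exonic_noncoding | intergenic
    expected_effect: str  # synonymous | nonsynonymous | stop_gained | none


@dataclass(frozen=True)
class UsageTruth:
    gene: str
    breed: str
    usage: tuple[float, ...]
    shifted: bool


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: dict[str, str]
    annotation: GeneAnnotation
    haplotypes: dict[str, dict[str, str]]
    variant_truth: list[VariantTruth]
    usage_truth: list[UsageTruth]
    usage: dict[str, dict[str, tuple[float, ...]]]
    novel_transcripts: list[TranscriptModel]
    sam_paths: dict[str, Path] = field(default_factory=dict)
    fragment_truth: pd.DataFrame | None = None


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def _random_sense_codon(rng: np.random.Generator) -> str:
    while True:
        codon = _random_bases(rng, 3)
        if codon not in STOP_CODONS and codon != "ATG":
            return codon


# ----------------------------------------------------------------------
# genome + annotation
# ----------------------------------------------------------------------

def simulate_genome_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], GeneAnnotation]:
    """Build a single-contig reference and its gene models.

    Genes are laid out left to right with ``gene_gap`` bp between
    spans. Each gene's primary isoform carries an open reading frame
    (ATG ... stop, no internal stops); where the ORF is long enough its
    sixth-from-last codon is forced to TGG so a single substitution can
    later create a premature stop truncating the final five amino
    acids. The first ``round(n_genes * two_isoform_frac)`` genes get a
    second isoform skipping one internal exon — both ends, hence the
    TSS, are shared.
    """
    rng = _rng(config, 1)
    n_two = int(round(config.n_genes * config.two_isoform_frac))
    contig = "chr1"
    chunks: list[str] = []
    cursor = 0

    def emit(seq: str) -> None:
        nonlocal cursor
        chunks.append(seq)
        cursor += len(seq)

    ann = GeneAnnotation(contig_lengths={})
    for gi in range(config.n_genes):
        emit(_random_bases(rng, config.gene_gap))
        two_iso = gi < n_two
        lo, hi = config.exons_per_gene
        if two_iso:
            lo = max(lo, 3)
            hi = max(hi, lo)
        n_ex = int(rng.integers(lo, hi + 1))
        exon_lens = [int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
                     for _ in range(n_ex)]
        intron_lens = [int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
                       for _ in range(n_ex - 1)]
        strand = "+" if rng.random() < 0.5 else "-"

        exons: list[Interval] = []
        pos = cursor
        for k, elen in enumerate(exon_lens):
            exons.append((pos, pos + elen))
            pos += elen
            if k < n_ex - 1:
                pos += intron_lens[k]
        gene_len_genomic = pos - cursor

        # design the spliced transcript sequence with a clean ORF
        T = sum(exon_lens)
        utr5 = min(30, max(0, T // 10))
        avail = T - 2 * utr5
        cds_len = max(6, avail - avail % 3)
        if cds_len > T - utr5:
            utr5 = 0
            cds_len = T - T % 3 - 3
        n_codons = cds_len // 3
        codons = ["ATG"] + [_random_sense_codon(rng) for _ in range(n_codons - 2)] + ["TAA"]
        if n_codons >= 8:
            codons[n_codons - 6] = "TGG"  # one substitution away from a stop
        tx_seq = (
            _random_bases(rng, utr5)
            + "".join(codons)
            + _random_bases(rng, T - utr5 - cds_len)
        )

        gene_id = f"gene{gi + 1:03d}"
        tx1_id = f"{gene_id}.t1"
        tx1 = TranscriptModel(tx1_id, gene_id, contig, strand, tuple(exons))
        cds_blocks = tuple(tx1.transcript_blocks(utr5, utr5 + cds_len))
        tx1 = TranscriptModel(tx1_id, gene_id, contig, strand, tuple(exons), cds_blocks)
        ann.add(tx1)
        if two_iso:
            skip = n_ex // 2  # internal: 1 <= skip <= n_ex - 2 for n_ex >= 3
            skip = min(max(skip, 1), n_ex - 2)
            exons2 = tuple(e for k, e in enumerate(exons) if k != skip)
            ann.add(TranscriptModel(f"{gene_id}.t2", gene_id, contig, strand, exons2))

        # write the transcript back into the genomic sequence
        genomic_exonic = tx_seq if strand == "+" else revcomp(tx_seq)
        gseq = list(_random_bases(rng, gene_len_genomic))
        off = 0
        for s, e in exons:
            gseq[s - cursor : e - cursor] = genomic_exonic[off : off + (e - s)]
            off += e - s
        emit("".join(gseq))

    emit(_random_bases(rng, config.gene_gap))
    reference = {contig: "".join(chunks)}
    ann.contig_lengths[contig] = len(reference[contig])
    return reference, ann


def intergenic_transcripts(
    annotation: GeneAnnotation, config: SimulationConfig
) -> list[TranscriptModel]:
    """Unannotated single-exon transcribed regions placed in gene gaps.

    ``far`` ones sit >= 1,000 bp from every gene span (so the intergenic
    rule should accept them), ``near`` ones < 1,000 bp (so it should
    not). They are returned separately and never added to the
    annotation.
    """
    spans = sorted(
        annotation.gene_span(g)[1:] for g in annotation.genes
    )
    out: list[TranscriptModel] = []
    contig = next(iter(annotation.contig_lengths))
    gap_idx = 0
    for kind, count, dist in (
        ("far", config.n_intergenic_far, config.intergenic_dist_far),
        ("near", config.n_intergenic_near, config.intergenic_dist_near),
    ):
        for k in range(count):
            if gap_idx >= len(spans) - 1:
                raise ConfigurationError("not enough gene gaps for intergenic transcripts")
            left_end = spans[gap_idx][1]
            start = left_end + dist
            end = start + config.intergenic_len
            if end > spans[gap_idx + 1][0]:
                raise ConfigurationError("intergenic transcript does not fit in gap")
            tid = f"novel_{kind}{k + 1}"
            out.append(
                TranscriptModel(tid, tid, contig, "+", ((start, end),))
            )
            gap_idx += 1
    return out


# ----------------------------------------------------------------------
# variant spiking
# ----------------------------------------------------------------------

def _codon_at(tx: TranscriptModel, contig_seq: str, gpos: int) -> tuple[str, int, int]:
    """Return (ref codon on transcript strand, offset within codon, codon index)."""
    t0, _ = tx.cds_transcript_interval
    tpos = tx.genome_to_transcript(gpos)
    cpos = tpos - t0
    idx, off = divmod(cpos, 3)
    codon = tx.spliced_sequence(contig_seq)[t0 + 3 * idx : t0 + 3 * idx + 3]
    return codon, off, idx


def _effect_of(ref_codon: str, alt_codon: str) -> str:
    from .divergence import classify_codon_change

    eff = classify_codon_change(ref_codon, alt_codon)
    if eff == "stop_lost":  # spiking avoids the stop codon, so this is a bug
        raise AssertionError("unexpected stop_lost in spiked truth")
    return eff


def spike_variants(
    reference: dict[str, str],
    annotation: GeneAnnotation,
    config: SimulationConfig,
) -> tuple[dict[str, dict[str, str]], list[VariantTruth]]:
    """Plant fixed between-breed differences and within-breed SNPs.

    Fixed differences each alter exactly one breed's haplotype;
    ``frac_coding_diffs`` of them fall inside CDS (the stop codon itself
    is never touched) and, when at least one coding difference is
    requested and a long-enough ORF exists, one of them converts the
    engineered TGG codon six from the ORF end into TGA — a premature
    stop truncating the last five amino acids. Within-breed SNPs are
    not written into haplotypes; their minor fractions drive allele
    sampling at read time.
    """
    rng = _rng(config, 2)
    contig = next(iter(reference))
    seq = reference[contig]
    haplotypes = {b: {contig: seq} for b in config.breeds}
    truth: list[VariantTruth] = []
    if config.n_fixed_diffs == 0 and config.n_within_snps == 0:
        return haplotypes, truth

    # candidate pools; primary (CDS-bearing) transcript per gene
    primary = {g: annotation.transcripts_of(g)[0] for g in annotation.genes}
    cds_tx: dict[int, TranscriptModel] = {}
    for tx in primary.values():
        if not tx.cds:
            continue
        t0, t1 = tx.cds_transcript_interval
        # exclude the stop codon (last three transcript positions of the CDS)
        for tp in range(t0, t1 - 3):
            cds_tx[tx.transcript_to_genome(tp)] = tx
    exon_union = sorted(
        {p for g in annotation.genes for s, e in annotation.gene_exon_union(g)
         for p in range(s, e)}
    )
    cds_all = {p for g in annotation.genes for s, e in annotation.gene_cds_union(g)
               for p in range(s, e)}
    utr_pool = [p for p in exon_union if p not in cds_all]
    cds_pool = sorted(cds_tx)

    used: set[int] = set()

    def classify(pos: int, alt: str) -> tuple[str, str]:
        if pos in cds_tx:
            tx = cds_tx[pos]
            codon, off, _ = _codon_at(tx, seq, pos)
            alt_t = alt if tx.strand == "+" else _COMP[alt]
            alt_codon = codon[:off] + alt_t + codon[off + 1 :]
            return "CDS", _effect_of(codon, alt_codon)
        if pos in cds_all:
            return "CDS", "nonsynonymous"  # CDS of a non-primary isoform; not sampled
        return "exonic_noncoding", "none"

    # ---- fixed between-breed differences
    n_coding = int(round(config.n_fixed_diffs * config.frac_coding_diffs))
    n_coding = min(n_coding, len(cds_pool))
    n_noncoding = config.n_fixed_diffs - n_coding
    if n_noncoding > len(utr_pool):
        raise ConfigurationError("more non-coding differences requested than exonic space")
    if n_coding > 0:
        # engineered premature stop: TGG -> TGA at codon n-6 of some ORF
        stop_site = None
        for tx in primary.values():
            if not tx.cds or tx.cds_length // 3 < 8:
                continue
            t0, _ = tx.cds_transcript_interval
            n_codons = tx.cds_length // 3
            tp = t0 + 3 * (n_codons - 6) + 2  # third base of the TGG codon
            gpos = tx.transcript_to_genome(tp)
            codon, off, _ = _codon_at(tx, seq, gpos)
            if codon == "TGG" and off == 2:
                stop_site = (gpos, tx)
                break
        if stop_site is not None:
            gpos, tx = stop_site
            alt = "A" if tx.strand == "+" else "T"  # TGG -> TGA on the transcript strand
            breed = config.breeds[0 if config.n_breeds == 1 else config.n_breeds - 1]
            haplotypes[breed][contig] = (
                haplotypes[breed][contig][:gpos] + alt + haplotypes[breed][contig][gpos + 1 :]
            )
            alleles = {b: (alt if b == breed else seq[gpos]) for b in config.breeds}
            truth.append(
                VariantTruth(contig, gpos, "fixed_between", alleles, "CDS", "stop_gained")
            )
            used.add(gpos)
            n_coding -= 1

    def sample_positions(pool: list[int], n: int) -> list[int]:
        avail = [p for p in pool if p not in used]
        if n > len(avail):
            raise ConfigurationError("more variants requested than available positions")
        picks = rng.choice(len(avail), size=n, replace=False)
        return [avail[i] for i in sorted(picks)]

    fixed_positions = [(p, True) for p in sample_positions(cds_pool, n_coding)]
    used.update(p for p, _ in fixed_positions)
    fixed_positions += [(p, False) for p in sample_positions(utr_pool, n_noncoding)]
    used.update(p for p, _ in fixed_positions)

    for i, (pos, _coding) in enumerate(fixed_positions):
        breed = config.breeds[i % config.n_breeds]
        ref_base = seq[pos]
        alt = rng.choice([b for b in BASES if b != ref_base])
        region, effect = classify(pos, alt)
        hap = haplotypes[breed][contig]
        haplotypes[breed][contig] = hap[:pos] + alt + hap[pos + 1 :]
        alleles = {b: (alt if b == breed else ref_base) for b in config.breeds}
        truth.append(VariantTruth(contig, pos, "fixed_between", alleles, region, effect))

    # ---- within-breed SNPs (applied at read-sampling time)
    for breed in config.breeds:
        positions = sample_positions(exon_union, config.n_within_snps)
        used.update(positions)
        for i, pos in enumerate(positions):
            major = seq[pos]
            minor = rng.choice([b for b in BASES if b != major])
            frac = config.minor_allele_fracs[i % len(config.minor_allele_fracs)]
            region, effect = classify(pos, str(minor))
            truth.append(
                VariantTruth(
                    contig, pos, "snp_within",
                    {breed: (major, str(minor), float(frac))}, region, effect,
                )
            )
    return haplotypes, truth


# ----------------------------------------------------------------------
# isoform usage
# ----------------------------------------------------------------------

def isoform_usage_profiles(
    annotation: GeneAnnotation, config: SimulationConfig
) -> tuple[dict[str, dict[str, tuple[float, ...]]], list[UsageTruth]]:
    """Per-breed per-gene isoform usage vectors plus truth records.

    Multi-isoform genes use ``usage_base`` everywhere except a leading
    ``usage_shift_frac`` fraction of them, which switch to
    ``usage_shifted`` in the last breed (the indicine-style pool).
    An explicit ``config.isoform_usage`` mapping overrides everything.
    """
    multi = [g for g in annotation.genes if len(annotation.genes[g]) >= 2]
    n_shifted = int(round(len(multi) * config.usage_shift_frac))
    shifted_genes = set(multi[:n_shifted])
    usage: dict[str, dict[str, tuple[float, ...]]] = {}
    truth: list[UsageTruth] = []
    for breed in config.breeds:
        usage[breed] = {}
        for gene, tids in annotation.genes.items():
            k = len(tids)
            if config.isoform_usage and gene in config.isoform_usage.get(breed, {}):
                u = tuple(config.isoform_usage[breed][gene])
            elif k == 1:
                u = (1.0,)
            else:
                shifted_here = gene in shifted_genes and breed == config.breeds[-1]
                u = tuple(config.usage_shifted if shifted_here else config.usage_base)
            if len(u) != k:
                raise ConfigurationError(f"usage vector for {gene} has wrong length")
            if abs(sum(u) - 1.0) > 1e-9:
                raise ConfigurationError(f"usage vector for {gene} does not sum to 1")
            usage[breed][gene] = u
            if k >= 2:
                truth.append(
                    UsageTruth(gene, breed, u,
                               gene in shifted_genes and breed == config.breeds[-1])
                )
    return usage, truth


# ----------------------------------------------------------------------
# fragment simulation
# ----------------------------------------------------------------------

def _sam_header(reference: dict[str, str]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in reference.items()],
    }


def _blocks_to_cigar(blocks: list[Interval]) -> list[tuple[int, int]]:
    cigar = []
    for i, (s, e) in enumerate(blocks):
        if i:
            cigar.append((3, s - blocks[i - 1][1]))  # N
        cigar.append((0, e - s))  # M
    return cigar


def simulate_fragments(
    breed_haplotypes: dict[str, dict[str, str]],
    annotation: GeneAnnotation,
    config: SimulationConfig,
    out_dir,
    variant_truth: list[VariantTruth] | None = None,
    usage: dict[str, dict[str, tuple[float, ...]]] | None = None,
    novel_transcripts: list[TranscriptModel] | None = None,
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Sample paired spliced fragments per breed and write one SAM each.

    In the default random mode, fragment starts are uniform along each
    transcript and the per-isoform fragment count targets
    ``depth * usage`` fragment coverage of the transcript. In tiling
    mode the transcript is cut into consecutive ``frag_len`` windows,
    each emitted ``round(depth * usage)`` times with the two mates
    partitioning the window — every transcribed base is then covered by
    exactly that many fragments. Mate orientation alternates (tiling)
    or is drawn fairly (random) so both strands support every allele at
    depth >= 2. Reads at within-breed SNP sites carry the minor allele
    with its truth probability, drawn once per fragment (one molecule);
    sequencing errors substitute uniformly among the three other bases.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 3)
    if usage is None:
        usage, _ = isoform_usage_profiles(annotation, config)
    snp_map: dict[str, dict[str, tuple[str, float]]] = {b: {} for b in config.breeds}
    for vt in variant_truth or []:
        if vt.kind != "snp_within":
            continue
        ((breed, (_major, minor, frac)),) = vt.breed_alleles.items()
        snp_map[breed][f"{vt.contig}:{vt.position}"] = (minor, frac)

    transcripts: list[tuple[str, TranscriptModel]] = [
        (tx.gene_id, tx) for tx in annotation
    ]
    for tx in novel_transcripts or []:
        transcripts.append((tx.gene_id, tx))

    sam_paths: dict[str, Path] = {}
    truth_rows: list[dict] = []
    header = _sam_header(
        {c: next(iter(breed_haplotypes.values()))[c] for c in annotation.contig_lengths}
    )
    footprint = min(config.frag_len, 2 * config.read_len)

    for breed in config.breeds:
        if breed not in breed_haplotypes:
            raise ConfigurationError(f"no haplotype for breed {breed!r}")
        path = out_dir / f"{breed}.sam"
        sam_paths[breed] = path
        hap = breed_haplotypes[breed]
        frag_no = 0
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            for gene_id, tx in transcripts:
                gene_usage = usage.get(breed, {}).get(gene_id)
                if gene_usage is None:
                    if gene_id in annotation.genes:
                        raise ConfigurationError(f"breed {breed!r} lacks usage for {gene_id}")
                    u = 1.0  # novel transcripts: full usage
                else:
                    iso_index = (
                        annotation.genes[gene_id].index(tx.transcript_id)
                        if gene_id in annotation.genes else 0
                    )
                    u = gene_usage[iso_index]
                L = tx.length
                contig_seq = hap[tx.contig]
                snps = [
                    (int(key.split(":")[1]), minor, frac)
                    for key, (minor, frac) in snp_map[breed].items()
                    if key.split(":")[0] == tx.contig
                ]
                tx_span = tx.span
                snps = [s for s in snps if tx_span[0] <= s[0] < tx_span[1]]

                if config.tiling:
                    copies = int(round(config.depth * u))
                    windows = [
                        (s, min(s + config.frag_len, L)) for s in range(0, L, config.frag_len)
                    ]
                    frags = [
                        (w, c % 2) for w in windows for c in range(copies)
                    ]
                else:
                    n = int(round(config.depth * u * L / footprint))
                    flen = min(config.frag_len, L)
                    starts = (
                        rng.integers(0, L - flen + 1, n) if L > flen else np.zeros(n, int)
                    )
                    orient = rng.integers(0, 2, n)
                    frags = [((int(s), int(s) + flen), int(o)) for s, o in zip(starts, orient)]

                for (f0, f1), orientation in frags:
                    frag_no += 1
                    _emit_fragment(
                        sam, tx, contig_seq, f0, f1, orientation,
                        f"{breed}.f{frag_no}", config, rng, snps,
                    )
                truth_rows.append(
                    {"breed": breed, "gene": gene_id, "transcript": tx.transcript_id,
                     "n_fragments": len(frags)}
                )
    fragment_truth = pd.DataFrame(
        truth_rows, columns=["breed", "gene", "transcript", "n_fragments"]
    )
    return sam_paths, fragment_truth


def _emit_fragment(
    sam: pysam.AlignmentFile,
    tx: TranscriptModel,
    contig_seq: str,
    f0: int,
    f1: int,
    orientation: int,
    qname: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    snps: list[tuple[int, str, float]],
) -> None:
    flen = f1 - f0
    if config.tiling:
        half = (flen + 1) // 2
        mate_ivals = [(f0, f0 + half), (f0 + half, f1)] if flen > 1 else [(f0, f1), (f0, f1)]
    else:
        r = min(config.read_len, flen)
        mate_ivals = [(f0, f0 + r), (f1 - r, f1)]

    # one molecule: decide SNP alleles once per fragment
    frag_blocks = tx.transcript_blocks(f0, f1)
    subs: dict[int, str] = {}
    for gpos, minor, frac in snps:
        if any(s <= gpos < e for s, e in frag_blocks) and rng.random() < frac:
            subs[gpos] = minor

    mates = []
    for t0, t1 in mate_ivals:
        blocks = tx.transcript_blocks(t0, t1)
        seq = list("".join(contig_seq[s:e] for s, e in blocks))
        gpositions = np.concatenate([np.arange(s, e) for s, e in blocks])
        for gpos, base in subs.items():
            hit = np.flatnonzero(gpositions == gpos)
            for h in hit:
                seq[h] = base
        n = len(seq)
        if config.error_mode == "low_quality":
            quals = np.full(n, config.qual_high, dtype=np.uint8)
        else:
            quals = np.where(
                rng.random(n) < config.qual_low_frac, config.qual_low, config.qual_high
            ).astype(np.uint8)
        if config.error_rate > 0:
            err = np.flatnonzero(rng.random(n) < config.error_rate)
            for k in err:
                seq[k] = BASES[
                    (BASES.index(seq[k]) + 1 + int(rng.integers(0, 3))) % 4
                ]
            if config.error_mode == "low_quality":
                quals[err] = config.qual_low
        mates.append((blocks, "".join(seq), quals))

    frag_lo = min(m[0][0][0] for m in mates)
    frag_hi = max(m[0][-1][1] for m in mates)
    tlen = frag_hi - frag_lo

    for mi, (blocks, seq, quals) in enumerate(mates):
        a = pysam.AlignedSegment()
        a.query_name = qname
        reverse = (orientation == 0 and mi == 1) or (orientation == 1 and mi == 0)
        other = mates[1 - mi]
        flag = 0x1 | 0x2 | (0x40 if mi == 0 else 0x80)
        if reverse:
            flag |= 0x10
        mate_reverse = not reverse
        if mate_reverse:
            flag |= 0x20
        a.flag = flag
        a.reference_id = sam.get_tid(tx.contig)
        a.reference_start = blocks[0][0]
        a.mapping_quality = 50
        a.cigartuples = _blocks_to_cigar(blocks)
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(int(q) + 33) for q in quals)
        )
        a.next_reference_id = a.reference_id
        a.next_reference_start = other[0][0][0]
        a.template_length = tlen if blocks[0][0] <= other[0][0][0] else -tlen
        a.set_tag("NH", 1)
        sam.write(a)


# ----------------------------------------------------------------------
# one-call driver
# ----------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig, out_dir) -> SimulatedDataset:
    """Run the full generator and write every artefact under ``out_dir``.

    Writes ``reference.fasta``, ``annotation.gtf``, per-breed haplotype
    FASTAs and SAMs, plus truth tables ``variant_truth.tsv``,
    ``usage_truth.tsv`` and ``fragment_truth.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference, annotation = simulate_genome_annotation(config)
    novel = intergenic_transcripts(annotation, config)
    haplotypes, variant_truth = spike_variants(reference, annotation, config)
    usage, usage_truth = isoform_usage_profiles(annotation, config)
    sam_paths, fragment_truth = simulate_fragments(
        haplotypes, annotation, config, out_dir,
        variant_truth=variant_truth, usage=usage, novel_transcripts=novel,
    )

    write_fasta(reference, out_dir / "reference.fasta")
    annotation.write_gtf(out_dir / "annotation.gtf")
    for breed, hap in haplotypes.items():
        write_fasta(hap, out_dir / f"haplotype_{breed}.fasta")
    variant_truth_table(variant_truth).to_csv(
        out_dir / "variant_truth.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"gene": u.gene, "breed": u.breed,
             "usage": ",".join(f"{x:.6g}" for x in u.usage), "shifted": u.shifted}
            for u in usage_truth
        ],
        columns=["gene", "breed", "usage", "shifted"],
    ).to_csv(out_dir / "usage_truth.tsv", sep="\t", index=False)
    fragment_truth.to_csv(out_dir / "fragment_truth.tsv", sep="\t", index=False)
    config.to_yaml(out_dir / "config.yaml")

    return SimulatedDataset(
        config=config, reference=reference, annotation=annotation,
        haplotypes=haplotypes, variant_truth=variant_truth,
        usage_truth=usage_truth, usage=usage, novel_transcripts=novel,
        sam_paths=sam_paths, fragment_truth=fragment_truth,
    )


def variant_truth_table(truth: list[VariantTruth]) -> pd.DataFrame:
    """Truth records as a flat table (1-based positions in ``pos``)."""
    rows = []
    for vt in truth:
        if vt.kind == "fixed_between":
            alleles = ";".join(f"{b}={a}" for b, a in sorted(vt.breed_alleles.items()))
        else:
            alleles = ";".join(
                f"{b}={maj}/{mino}:{frac:.4g}"
                for b, (maj, mino, frac) in sorted(vt.breed_alleles.items())
            )
        rows.append(
            {"contig": vt.contig, "pos": vt.position + 1, "kind": vt.kind,
             "alleles": alleles, "region": vt.region,
             "expected_effect": vt.expected_effect}
        )
    return pd.DataFrame(
        rows, columns=["contig", "pos", "kind", "alleles", "region", "expected_effect"]
    )
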