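"""Alternative-splicing event classification and differential usage.

Analysis is restricted to genes whose isoforms all share a single
transcription start site and that express more than one isoform, so
alternative first exons never confound the comparison. For each
isoform pair the exon/intron chains are compared (in transcript-strand
orientation) and events are classified into six categories: exon
skipping, alternative 5' splice site, alternative 3' splice site,
intron retention, mutually exclusive exons, and alternative last exon.
Events are deduplicated across isoform pairs by (category, involved
coordinates).

Differential isoform usage between two breeds is measured by the
square root of the Jensen-Shannon divergence (entropy in bits) between
the two relative-usage distributions, with significance from a
multinomial bootstrap under the pooled null.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import bh_fdr
from .genome import GeneAnnotation, Interval, TranscriptModel

log = logging.getLogger(__name__)

EXON_SKIPPING = "exon_skipping"
ALT_5SS = "alt_5ss"
ALT_3SS = "alt_3ss"
INTRON_RETENTION = "intron_retention"
MUTUALLY_EXCLUSIVE = "mutually_exclusive"
ALT_LAST_EXON = "alt_last_exon"
ALT_FIRST_EXON = "alt_first_exon"  # detected only when explicitly enabled

CATEGORIES = (
    EXON_SKIPPING, ALT_5SS, ALT_3SS, INTRON_RETENTION,
    MUTUALLY_EXCLUSIVE, ALT_LAST_EXON,
)


@dataclass(frozen=True)
class SpliceEvent:
    gene: str
    category: str
    isoforms: tuple[str, str]
    coordinates: tuple[Interval, ...]
    strand: str

    @property
    def key(self) -> tuple:
        return (self.category, self.coordinates)


def single_tss_multi_isoform(
    annotation: GeneAnnotation,
) -> dict[str, list[str]]:
    """Genes whose isoforms all share one TSS and number >= 2.

    Returns gene id -> transcript ids (the gene's single TSS group).
    """
    out: dict[str, list[str]] = {}
    for gene, tids in annotation.genes.items():
        if len(tids) < 2:
            continue
        tss = {annotation.transcripts[t].tss for t in tids}
        if len(tss) == 1:
            out[gene] = list(tids)
    return out


def _pair_events(a: TranscriptModel, b: TranscriptModel) -> list[SpliceEvent]:
    """Classify the events distinguishing one isoform pair."""
    events: list[SpliceEvent] = []
    strand = a.strand
    ia, ib = set(a.introns), set(b.introns)
    exons_a, exons_b = list(a.exons), list(b.exons)
    pair = (a.transcript_id, b.transcript_id)
    gene = a.gene_id

    def emit(category: str, coords: tuple[Interval, ...]) -> None:
        events.append(SpliceEvent(gene, category, pair, tuple(sorted(coords)), strand))

    def skipped_exons(x: TranscriptModel, introns_other: set) -> list[tuple[Interval, Interval]]:
        """Internal exons of x bridged by a single intron of the other."""
        out = []
        for k in range(1, len(x.exons) - 1):
            exon = x.exons[k]
            bridge = (x.exons[k - 1][1], x.exons[k + 1][0])
            if bridge in introns_other:
                out.append((exon, bridge))
        return out

    skips_a = skipped_exons(a, ib)
    skips_b = skipped_exons(b, ia)

    # mutually exclusive: one middle exon each between the same flanks,
    # non-overlapping, and never co-occurring in either isoform
    mx_pairs = set()
    for k in range(1, len(exons_a) - 1):
        ea = exons_a[k]
        flank = (exons_a[k - 1][1], exons_a[k + 1][0])
        for j in range(1, len(exons_b) - 1):
            eb = exons_b[j]
            if (exons_b[j - 1][1], exons_b[j + 1][0]) != flank:
                continue
            if ea == eb or (ea[0] < eb[1] and eb[0] < ea[1]):
                continue  # same or overlapping middle exons
            if ea in exons_b or eb in exons_a:
                continue  # an isoform includes both middle exons
            mx_pairs.add(tuple(sorted((ea, eb))))
            emit(MUTUALLY_EXCLUSIVE, (ea, eb))
    mx_exons = {e for p in mx_pairs for e in p}

    for exon, _bridge in skips_a + skips_b:
        if exon not in mx_exons:
            emit(EXON_SKIPPING, (exon,))

    # intron retention: an intron of one lies inside an exon of the other
    for intr in ia - ib:
        if any(s <= intr[0] and intr[1] <= e for s, e in exons_b):
            emit(INTRON_RETENTION, (intr,))
    for intr in ib - ia:
        if any(s <= intr[0] and intr[1] <= e for s, e in exons_a):
            emit(INTRON_RETENTION, (intr,))

    # alternative donor/acceptor: intron pairs sharing one boundary,
    # where the shorter intron's extra exonic run covers the difference
    def exon_covers(x: TranscriptModel, s: int, e: int) -> bool:
        return any(xs <= s and e <= xe for xs, xe in x.exons)

    for intr_a, intr_b in itertools.product(ia - ib, ib - ia):
        sa, ea = intr_a
        sb, eb = intr_b
        if ea == eb and sa != sb:
            # shared genomic end; differing genomic start
            lo, hi = min(sa, sb), max(sa, sb)
            short_side = a if sa > sb else b  # isoform whose exon extends to hi
            if not exon_covers(short_side, lo, hi):
                continue
            category = ALT_5SS if strand == "+" else ALT_3SS
            emit(category, ((lo, hi),))
        elif sa == sb and ea != eb:
            lo, hi = min(ea, eb), max(ea, eb)
            short_side = a if ea < eb else b  # isoform whose exon starts at lo
            if not exon_covers(short_side, lo, hi):
                continue
            category = ALT_3SS if strand == "+" else ALT_5SS
            emit(category, ((lo, hi),))

    # alternative terminal exons: shared boundary junction into
    # non-overlapping terminal exons
    def terminal_alternative(last: bool) -> None:
        if len(a.introns) == 0 or len(b.introns) == 0:
            return
        intr_a = a.introns[-1] if last else a.introns[0]
        intr_b = b.introns[-1] if last else b.introns[0]
        term_a = a.exons[-1] if last else a.exons[0]
        term_b = b.exons[-1] if last else b.exons[0]
        shared = intr_a[0] == intr_b[0] if last else intr_a[1] == intr_b[1]
        if not shared or intr_a == intr_b:
            return
        if term_a[0] < term_b[1] and term_b[0] < term_a[1]:
            return  # overlapping terminal exons: an alt splice site instead
        emit(ALT_LAST_EXON if last else ALT_FIRST_EXON, (term_a, term_b))

    if strand == "+":
        terminal_alternative(last=True)
        terminal_alternative(last=False)
    else:
        # transcript-last exon is genomic-first
        def terminal_alternative_minus(transcript_last: bool) -> None:
            intr_a = a.introns[0] if transcript_last else a.introns[-1]
            intr_b = b.introns[0] if transcript_last else b.introns[-1]
            term_a = a.exons[0] if transcript_last else a.exons[-1]
            term_b = b.exons[0] if transcript_last else b.exons[-1]
            shared = (
                intr_a[1] == intr_b[1] if transcript_last else intr_a[0] == intr_b[0]
            )
            if not shared or intr_a == intr_b:
                return
            if term_a[0] < term_b[1] and term_b[0] < term_a[1]:
                return
            emit(ALT_LAST_EXON if transcript_last else ALT_FIRST_EXON, (term_a, term_b))

        if a.introns and b.introns:
            terminal_alternative_minus(True)
            terminal_alternative_minus(False)

    return events


def classify_events(
    annotation: GeneAnnotation,
    gene: str,
    include_alt_first_exon: bool = False,
) -> list[SpliceEvent]:
    """Deduplicated splice events among one gene's isoform pairs.

    Alternative-first-exon events are classified internally but
    dropped unless ``include_alt_first_exon`` — under the single-TSS
    restriction they cannot occur, and the headline analysis never
    interrogates them.
    """
    txs = annotation.transcripts_of(gene)
    seen: dict[tuple, SpliceEvent] = {}
    for a, b in itertools.combinations(txs, 2):
        for ev in _pair_events(a, b):
            if ev.category == ALT_FIRST_EXON and not include_alt_first_exon:
                continue
            seen.setdefault(ev.key, ev)
    return list(seen.values())


def events_table(events: list[SpliceEvent]) -> pd.DataFrame:
    rows = [
        {
            "gene": ev.gene,
            "category": ev.category,
            "isoforms": "|".join(ev.isoforms),
            "strand": ev.strand,
            "coordinates": ";".join(f"{s + 1}-{e}" for s, e in ev.coordinates),
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=["gene", "category", "isoforms", "strand", "coordinates"])


def write_events_bed(events: list[SpliceEvent], contig_of: dict[str, str], path) -> None:
    """Events as BED12 (one record per event, blocks = involved intervals)."""
    with open(path, "w") as fh:
        for ev in events:
            contig = contig_of[ev.gene]
            start = min(s for s, _ in ev.coordinates)
            end = max(e for _, e in ev.coordinates)
            blocks = sorted(ev.coordinates)
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - start) for s, _ in blocks)
            name = f"{ev.gene}:{ev.category}"
            fh.write(
                f"{contig}\t{start}\t{end}\t{name}\t0\t{ev.strand}\t{start}\t{end}"
                f"\t0,0,0\t{len(blocks)}\t{sizes}\t{starts}\n"
            )


# ----------------------------------------------------------------------
# Jensen-Shannon usage statistic
# ----------------------------------------------------------------------

def _entropy_bits(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.maximum(p, 1e-300)), 0.0)
    return -terms.sum(axis=-1)


def sqrt_jsd(p, q) -> float:
    """Square root of the Jensen-Shannon divergence in bits.

    JS(P,Q) = H(M) - (H(P) + H(Q))/2 with M the midpoint distribution;
    the square root is a metric bounded in [0, 1] (log base 2).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions have different dimensions")
    for v in (p, q):
        if abs(v.sum() - 1.0) > 1e-6 or (v < 0).any():
            raise ValueError("inputs must be probability vectors")
    m = (p + q) / 2.0
    js = _entropy_bits(m) - (_entropy_bits(p) + _entropy_bits(q)) / 2.0
    return float(np.sqrt(max(js, 0.0)))


@dataclass(frozen=True)
class DiffSpliceResult:
    gene: str
    statistic: float
    p: float
    q: float = float("nan")
    testable: bool = True


def diff_splicing_test(
    counts_a,
    counts_b,
    n_boot: int = 10000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[float, float]:
    """Bootstrap test of equal isoform usage between two breeds.

    The observed statistic is the √JS divergence between the two
    normalized count vectors. The null resamples ``n_boot`` pairs of
    multinomial counts (original totals) from the pooled proportions;
    p = (1 + #{null >= observed}) / (n_boot + 1).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length count vectors over >= 2 isoforms")
    ta, tb = a.sum(), b.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("untestable: a breed has zero fragments")
    obs = sqrt_jsd(a / ta, b / tb)
    pooled = (a + b) / (ta + tb)
    # integer totals for the multinomial draw (EM counts may be fractional)
    na, nb = max(int(round(ta)), 1), max(int(round(tb)), 1)
    draws_a = rng.multinomial(na, pooled, size=n_boot) / na
    draws_b = rng.multinomial(nb, pooled, size=n_boot) / nb
    m = (draws_a + draws_b) / 2.0
    js = _entropy_bits(m) - (_entropy_bits(draws_a) + _entropy_bits(draws_b)) / 2.0
    null = np.sqrt(np.maximum(js, 0.0))
    p = (1.0 + float(np.sum(null >= obs - 1e-12))) / (n_boot + 1.0)
    return obs, p


def diff_splicing_screen(
    usage_counts: dict[str, tuple[np.ndarray, np.ndarray]],
    n_boot: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Test many genes and control FDR across the testable ones.

    ``usage_counts`` maps gene -> (counts in breed A, counts in breed
    B), typically EM expected isoform counts of the gene's single TSS
    group. Genes with all-zero counts in a breed are flagged
    untestable and excluded from the FDR correction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in sorted(usage_counts):
        a, b = usage_counts[gene]
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.sum() <= 0 or b.sum() <= 0:
            rows.append({"gene": gene, "statistic": np.nan, "p": np.nan,
                         "testable": False})
            log.warning("gene %s untestable (zero fragments in a breed)", gene)
            continue
        stat, p = diff_splicing_test(a, b, n_boot=n_boot, rng=rng)
        rows.append({"gene": gene, "statistic": stat, "p": p, "testable": True})
    out = pd.DataFrame(rows, columns=["gene", "statistic", "p", "testable"])
    out["q"] = np.nan
    mask = out["testable"]
    if mask.any():
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out
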