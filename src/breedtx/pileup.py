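"""Per-site allele counting and monomorphic/polymorphic site calling.

A pooled RNA-seq library yields, at each covered base, a distribution
of read alleles rather than a genotype. Sites with at least
``min_coverage`` fragments are classified with the pooled-SNP filters:
a site is *polymorphic* when (1) the minor allele holds at least
``minor_frac`` of the reads, (2) both of the top two alleles are seen
on both strands with base quality >= ``min_qual``, and (3) the top two
alleles jointly account for at least ``top2_frac`` of the reads. It is
*monomorphic* (with a consensus base) when the minor fraction is below
``minor_frac``, the top base alone reaches ``top2_frac`` dominance, and
that base has both-strand quality support. Everything else surveyed is
*ambiguous*; sites under ``min_coverage`` are *uncallable*.

Counting is fragment-deduplicated: only primary, uniquely mapped
(``NH == 1``), non-duplicate records contribute, spliced segments skip
their introns, and where mates overlap the higher-quality base call of
the pair is kept so one molecule is never counted twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_EPS = 1e-9  # integer-count comparisons against fractional thresholds

STATUS_UNCALLABLE = "uncallable"
STATUS_MONOMORPHIC = "monomorphic"
STATUS_POLYMORPHIC = "polymorphic"
STATUS_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CallingThresholds:
    """Coverage and polymorphism filters (defaults: the pooled-SNP rules)."""

    min_coverage: int = 10
    minor_frac: float = 0.10
    min_qual: int = 20
    top2_frac: float = 0.90

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0 < self.minor_frac <= 0.5:
            raise ValueError("minor_frac must be in (0, 0.5]")
        if not 0 < self.top2_frac <= 1:
            raise ValueError("top2_frac must be in (0, 1]")


@dataclass(frozen=True)
class SiteCall:
    breed: str
    contig: str
    position: int  # 0-based
    status: str
    consensus: str | None
    depth: int


class AlleleCountTable:
    """Dense per-contig allele counts for one breed's library.

    ``counts[contig]`` has shape ``(contig_len, 4 bases, 2 strands)``;
    ``counts_q20`` is the same restricted to base quality >=
    ``min_qual``. ``depth`` at a site is the fragment-deduplicated
    total over bases and strands.
    """

    def __init__(self, breed: str, contig_lengths: dict[str, int], min_qual: int = 20):
        self.breed = breed
        self.min_qual = min_qual
        self.counts = {
            c: np.zeros((length, 4, 2), dtype=np.int32)
            for c, length in contig_lengths.items()
        }
        self.counts_q20 = {
            c: np.zeros((length, 4, 2), dtype=np.int32)
            for c, length in contig_lengths.items()
        }
        self.n_fragments = 0
        self.n_skipped = 0

    def depth(self, contig: str) -> np.ndarray:
        return self.counts[contig].sum(axis=(1, 2))

    def site(self, contig: str, position: int) -> tuple[np.ndarray, np.ndarray]:
        return self.counts[contig][position], self.counts_q20[contig][position]


def _usable(read: pysam.AlignedSegment) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
        return False
    if read.has_tag("NH") and read.get_tag("NH") != 1:
        return False
    return True


def _read_base_calls(read: pysam.AlignedSegment):
    """Arrays (refpos, base index, qual) for aligned M bases; None on error."""
    seq = read.query_sequence
    quals = read.query_qualities
    if seq is None or quals is None or len(seq) != len(quals):
        return None
    refpos_parts, qpos_parts = [], []
    rpos = read.reference_start
    qpos = 0
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            refpos_parts.append(np.arange(rpos, rpos + length))
            qpos_parts.append(np.arange(qpos, qpos + length))
            rpos += length
            qpos += length
        elif op in (2, 3):  # D, N: reference only
            rpos += length
        elif op in (1, 4):  # I, S: query only
            qpos += length
        elif op == 5:  # H
            pass
        else:
            return None
    if not refpos_parts:
        return None
    refpos = np.concatenate(refpos_parts)
    qpos_all = np.concatenate(qpos_parts)
    if qpos_all[-1] >= len(seq):
        return None
    base_idx = np.array([_BASE_INDEX.get(seq[i], -1) for i in qpos_all], dtype=np.int64)
    qual = np.asarray(quals, dtype=np.int64)[qpos_all]
    keep = base_idx >= 0
    return refpos[keep], base_idx[keep], qual[keep]


def build_pileup(
    sam_path,
    thresholds: CallingThresholds | None = None,
    breed: str | None = None,
) -> AlleleCountTable:
    """Tally fragment-deduplicated allele counts from one SAM file."""
    thresholds = thresholds or CallingThresholds()
    sam_path = Path(sam_path)
    breed = breed or sam_path.stem
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        contig_lengths = dict(zip(sam.references, sam.lengths))
        table = AlleleCountTable(breed, contig_lengths, min_qual=thresholds.min_qual)
        fragments: dict[str, list] = {}
        for read in sam:
            if not _usable(read):
                continue
            calls = _read_base_calls(read)
            if calls is None:
                table.n_skipped += 1
                log.warning("skipping malformed record %s", read.query_name)
                continue
            strand = 1 if read.is_reverse else 0
            fragments.setdefault(read.query_name, []).append(
                (read.reference_name, strand, *calls)
            )
    for name, mates in fragments.items():
        table.n_fragments += 1
        _add_fragment(table, mates, thresholds.min_qual)
    return table


def _add_fragment(table: AlleleCountTable, mates: list, min_qual: int) -> None:
    by_contig: dict[str, list] = {}
    for contig, strand, refpos, base_idx, qual in mates:
        by_contig.setdefault(contig, []).append((strand, refpos, base_idx, qual))
    for contig, parts in by_contig.items():
        counts = table.counts[contig]
        counts_q = table.counts_q20[contig]
        if len(parts) > 1:
            covered = [set(p[1].tolist()) for p in parts]
            overlap = set.intersection(*covered) if len(covered) > 1 else set()
        else:
            overlap = set()
        if not overlap:
            for strand, refpos, base_idx, qual in parts:
                np.add.at(counts, (refpos, base_idx, strand), 1)
                qmask = qual >= min_qual
                np.add.at(counts_q, (refpos[qmask], base_idx[qmask], strand), 1)
        else:
            # overlapping mates: one molecule — keep the higher-quality call
            best: dict[int, tuple[int, int, int]] = {}
            for strand, refpos, base_idx, qual in parts:
                for p, b, q in zip(refpos.tolist(), base_idx.tolist(), qual.tolist()):
                    prev = best.get(p)
                    if prev is None or q > prev[2]:
                        best[p] = (b, strand, q)
            for p, (b, strand, q) in best.items():
                counts[p, b, strand] += 1
                if q >= min_qual:
                    counts_q[p, b, strand] += 1


def call_site(
    counts: np.ndarray,
    counts_q20: np.ndarray,
    thresholds: CallingThresholds | None = None,
) -> tuple[str, str | None, int]:
    """Classify one site; returns (status, consensus or None, depth).

    ``counts``/``counts_q20`` are (4 bases, 2 strands) arrays. Ties in
    the base ranking break by the fixed order A < C < G < T.
    """
    thresholds = thresholds or CallingThresholds()
    counts = np.asarray(counts)
    counts_q20 = np.asarray(counts_q20)
    base_tot = counts.sum(axis=1)
    depth = int(base_tot.sum())
    if depth < thresholds.min_coverage:
        return STATUS_UNCALLABLE, None, depth
    order = np.argsort(-base_tot, kind="stable")
    top1, top2 = int(order[0]), int(order[1])
    c1, c2 = int(base_tot[top1]), int(base_tot[top2])
    f_minor = c2 / depth
    both_strands = lambda b: counts_q20[b, 0] > 0 and counts_q20[b, 1] > 0
    if (
        f_minor >= thresholds.minor_frac - _EPS
        and both_strands(top1)
        and both_strands(top2)
        and c1 + c2 >= thresholds.top2_frac * depth - _EPS
    ):
        return STATUS_POLYMORPHIC, None, depth
    if (
        f_minor < thresholds.minor_frac - _EPS
        and c1 >= thresholds.top2_frac * depth - _EPS
        and both_strands(top1)
    ):
        return STATUS_MONOMORPHIC, BASES[top1], depth
    return STATUS_AMBIGUOUS, None, depth


def call_all(
    table: AlleleCountTable,
    thresholds: CallingThresholds | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Call every surveyed site of one breed; vectorized over contigs.

    Returns a site-call table (0-based ``position``) restricted to
    sites with any coverage, plus a summary with ``n_surveyed`` (depth
    >= min_coverage), ``n_polymorphic`` and the SNP percentage
    ``100 * n_polymorphic / n_surveyed`` rounded to 3 decimals.
    """
    thresholds = thresholds or CallingThresholds()
    frames = []
    n_surveyed = 0
    n_polymorphic = 0
    for contig, counts in table.counts.items():
        base_tot = counts.sum(axis=2)  # (L, 4)
        depth = base_tot.sum(axis=1)
        covered = np.flatnonzero(depth > 0)
        if covered.size == 0:
            continue
        bt = base_tot[covered]
        dp = depth[covered]
        order = np.argsort(-bt, axis=1, kind="stable")
        top1 = order[:, 0]
        top2 = order[:, 1]
        rows = np.arange(covered.size)
        c1 = bt[rows, top1]
        c2 = bt[rows, top2]
        f_minor = c2 / dp
        q = table.counts_q20[contig][covered]
        both = (q[:, :, 0] > 0) & (q[:, :, 1] > 0)  # (n, 4)
        both1 = both[rows, top1]
        both2 = both[rows, top2]
        callable_ = dp >= thresholds.min_coverage
        minor_hi = f_minor >= thresholds.minor_frac - _EPS
        poly = (
            callable_ & minor_hi & both1 & both2
            & (c1 + c2 >= thresholds.top2_frac * dp - _EPS)
        )
        mono = (
            callable_ & ~minor_hi & both1
            & (c1 >= thresholds.top2_frac * dp - _EPS)
        )
        status = np.full(covered.size, STATUS_AMBIGUOUS, dtype=object)
        status[~callable_] = STATUS_UNCALLABLE
        status[poly] = STATUS_POLYMORPHIC
        status[mono] = STATUS_MONOMORPHIC
        consensus = np.full(covered.size, None, dtype=object)
        consensus[mono] = np.array(list(BASES), dtype=object)[top1[mono]]
        frames.append(
            pd.DataFrame(
                {
                    "breed": table.breed,
                    "contig": contig,
                    "position": covered,
                    "status": status,
                    "consensus": consensus,
                    "depth": dp,
                }
            )
        )
        n_surveyed += int(callable_.sum())
        n_polymorphic += int(poly.sum())
    if frames:
        calls = pd.concat(frames, ignore_index=True)
    else:
        calls = pd.DataFrame(
            columns=["breed", "contig", "position", "status", "consensus", "depth"]
        )
        log.warning("empty allele-count table for breed %s", table.breed)
    from .report import round_half_up

    pct = (
        round_half_up(100.0 * n_polymorphic / n_surveyed, 3) if n_surveyed else 0.0
    )
    summary = {
        "breed": table.breed,
        "n_surveyed": n_surveyed,
        "n_polymorphic": n_polymorphic,
        "percent_polymorphic": pct,
    }
    return calls, summary


def write_site_calls(calls: pd.DataFrame, path) -> None:
    """Site calls as TSV with 1-based positions."""
    out = calls.copy()
    out["pos"] = out["position"] + 1
    out[["breed", "contig", "pos", "status", "consensus", "depth"]].to_csv(
        path, sep="\t", index=False, na_rep="."
    )


def write_polymorphic_vcf(calls: pd.DataFrame, table: AlleleCountTable,
                          reference: dict[str, str], path) -> None:
    """Polymorphic sites as a minimal VCF v4.2 (AF from read fractions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele read fraction">\n')
        fh.write(f"##source=breedtx,breed={table.breed}\n")
        for contig, counts in table.counts.items():
            fh.write(f"##contig=<ID={contig},length={counts.shape[0]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        poly = calls[calls["status"] == STATUS_POLYMORPHIC]
        for row in poly.itertuples():
            base_tot = table.counts[row.contig][row.position].sum(axis=1)
            depth = base_tot.sum()
            order = np.argsort(-base_tot, kind="stable")
            ref_base = reference[row.contig][row.position]
            alts = [
                BASES[b] for b in order[:2] if BASES[b] != ref_base and base_tot[b] > 0
            ]
            if not alts:
                continue
            af = ",".join(f"{base_tot[_BASE_INDEX[a]] / depth:.4g}" for a in alts)
            fh.write(
                f"{row.contig}\t{row.position + 1}\t.\t{ref_base}\t{','.join(alts)}"
                f"\t.\tPASS\tAF={af}\n"
            )
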