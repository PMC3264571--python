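"""Between-breed fixed differences and their coding consequences.

A *fixed difference* is a site that is monomorphic-callable in every
breed pool but whose consensus bases differ between at least one pair
of breeds. The number of sites monomorphic in all breeds
(``n_determinable``) is the denominator of the divergence percentages.
Differences falling in coding sequence are classified by translating
the reference versus alternate codon (synonymous / nonsynonymous /
stop_gained / stop_lost); exonic positions outside any CDS are
"exonic_noncoding" and everything else "other".
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .genome import GeneAnnotation, TranscriptModel
from .pileup import AlleleCountTable, STATUS_MONOMORPHIC

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

REGION_CDS = "CDS"
REGION_EXONIC_NONCODING = "exonic_noncoding"
REGION_OTHER = "other"


def translate_codon(codon: str) -> str:
    """Single-letter amino acid, '*' for stop (standard genetic code)."""
    return str(Seq(codon).translate())


def classify_codon_change(ref_codon: str, alt_codon: str) -> str:
    """Effect of swapping ``ref_codon`` for ``alt_codon`` in frame."""
    aa_ref = translate_codon(ref_codon)
    aa_alt = translate_codon(alt_codon)
    if aa_alt == "*" and aa_ref != "*":
        return "stop_gained"
    if aa_ref == "*" and aa_alt != "*":
        return "stop_lost"
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


@dataclass(frozen=True)
class BreedDifference:
    contig: str
    position: int  # 0-based
    breed_consensus: dict
    differing_pairs: frozenset  # of (breed, breed) tuples, input order
    region: str = REGION_OTHER
    effect: str = "none"
    gene: str | None = None
    transcript: str | None = None
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None


def cross_breed_differences(
    calls_by_breed: dict[str, pd.DataFrame],
) -> tuple[list[BreedDifference], dict[tuple[str, str], int], int]:
    """Sites monomorphic in all breeds whose consensus differs in a pair.

    Returns the differences, per-pair difference counts, and
    ``n_determinable`` — the count of sites monomorphic-callable in
    every breed.
    """
    breeds = list(calls_by_breed)
    if len(breeds) < 2:
        raise ValueError("need at least two breeds to compare")
    merged: pd.DataFrame | None = None
    for breed in breeds:
        calls = calls_by_breed[breed]
        mono = calls[calls["status"] == STATUS_MONOMORPHIC][
            ["contig", "position", "consensus"]
        ].rename(columns={"consensus": breed})
        merged = mono if merged is None else merged.merge(
            mono, on=["contig", "position"], how="inner"
        )
    n_determinable = len(merged)
    if n_determinable == 0:
        log.warning("no site is monomorphic-callable in all breeds")
    pairs = list(itertools.combinations(breeds, 2))
    pair_counts = {p: 0 for p in pairs}
    diffs: list[BreedDifference] = []
    cons_matrix = merged[breeds].to_numpy()
    differs_any = (cons_matrix != cons_matrix[:, [0]]).any(axis=1)
    for row, cons in zip(merged.loc[differs_any].itertuples(), cons_matrix[differs_any]):
        consensus = dict(zip(breeds, cons))
        differing = frozenset(
            (a, b) for a, b in pairs if consensus[a] != consensus[b]
        )
        for p in differing:
            pair_counts[p] += 1
        diffs.append(
            BreedDifference(
                contig=row.contig, position=int(row.position),
                breed_consensus=consensus, differing_pairs=differing,
            )
        )
    return diffs, pair_counts, n_determinable


class EffectAnnotator:
    """Locates each position in the gene models and classifies effects.

    When a position lies in the CDS of several transcripts, the effect
    is reported for the transcript with the longest CDS (ties broken by
    transcript id) so each site gets a single deterministic label.
    """

    def __init__(self, annotation: GeneAnnotation, reference: dict[str, str]):
        self.annotation = annotation
        self.reference = reference
        self._cds_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for tx in annotation:
            ct = self._cds_trees.setdefault(tx.contig, IntervalTree())
            et = self._exon_trees.setdefault(tx.contig, IntervalTree())
            for s, e in tx.cds:
                ct.addi(s, e, tx)
            for s, e in tx.exons:
                et.addi(s, e, tx)
        self._spliced_cache: dict[str, str] = {}

    def _spliced(self, tx: TranscriptModel) -> str:
        if tx.transcript_id not in self._spliced_cache:
            self._spliced_cache[tx.transcript_id] = tx.spliced_sequence(
                self.reference[tx.contig]
            )
        return self._spliced_cache[tx.transcript_id]

    def locate(self, contig: str, position: int) -> tuple[str, TranscriptModel | None]:
        if contig not in self.reference:
            raise KeyError(f"position on unknown contig {contig!r}")
        if not 0 <= position < len(self.reference[contig]):
            raise IndexError(f"{contig}:{position} outside contig")
        hits = self._cds_trees.get(contig, IntervalTree())[position]
        if hits:
            tx = min(hits, key=lambda h: (-h.data.cds_length, h.data.transcript_id)).data
            return REGION_CDS, tx
        if self._exon_trees.get(contig, IntervalTree())[position]:
            return REGION_EXONIC_NONCODING, None
        return REGION_OTHER, None

    def annotate(self, diff: BreedDifference) -> BreedDifference:
        region, tx = self.locate(diff.contig, diff.position)
        if region != REGION_CDS:
            return replace(diff, region=region, effect="none")
        assert tx is not None
        ref_base = self.reference[diff.contig][diff.position]
        alt_bases = sorted(set(diff.breed_consensus.values()) - {ref_base})
        if not alt_bases:
            raise ValueError(
                f"{diff.contig}:{diff.position}: no breed consensus differs from reference"
            )
        alt = alt_bases[0]
        t0, _ = tx.cds_transcript_interval
        tpos = tx.genome_to_transcript(diff.position)
        idx, off = divmod(tpos - t0, 3)
        spliced = self._spliced(tx)
        codon_ref = spliced[t0 + 3 * idx : t0 + 3 * idx + 3]
        alt_t = alt if tx.strand == "+" else _COMP[alt]
        codon_alt = codon_ref[:off] + alt_t + codon_ref[off + 1 :]
        return replace(
            diff,
            region=REGION_CDS,
            effect=classify_codon_change(codon_ref, codon_alt),
            gene=tx.gene_id,
            transcript=tx.transcript_id,
            codon_ref=codon_ref,
            codon_alt=codon_alt,
            aa_ref=translate_codon(codon_ref),
            aa_alt=translate_codon(codon_alt),
        )


def annotate_effect(
    diff: BreedDifference,
    annotation: GeneAnnotation,
    reference: dict[str, str],
) -> BreedDifference:
    """Complete one difference record (convenience over EffectAnnotator)."""
    return EffectAnnotator(annotation, reference).annotate(diff)


def annotate_all(
    diffs: list[BreedDifference],
    annotation: GeneAnnotation,
    reference: dict[str, str],
) -> list[BreedDifference]:
    ann = EffectAnnotator(annotation, reference)
    return [ann.annotate(d) for d in diffs]


def genes_with_nonsynonymous(diffs: list[BreedDifference]) -> set[str]:
    """Distinct genes carrying a nonsynonymous (or stop) difference."""
    return {
        d.gene for d in diffs
        if d.gene and d.effect in ("nonsynonymous", "stop_gained", "stop_lost")
    }


def genes_with_cds_coverage(
    annotation: GeneAnnotation,
    pileup: AlleleCountTable,
    min_frac: float = 0.5,
    min_cov: int = 10,
) -> set[str]:
    """Genes whose CDS is sufficiently covered by deduplicated fragments.

    A gene passes when at least ``min_frac`` of its CDS-union bases have
    fragment depth >= ``min_cov`` (boundary inclusive).
    """
    out: set[str] = set()
    depth_cache = {c: pileup.depth(c) for c in pileup.counts}
    for gene in annotation.genes:
        cds = annotation.gene_cds_union(gene)
        if not cds:
            log.info("gene %s has no CDS; excluded from coverage filter", gene)
            continue
        contig = annotation.transcripts_of(gene)[0].contig
        depth = depth_cache.get(contig)
        if depth is None:
            continue
        total = sum(e - s for s, e in cds)
        covered = sum(int((depth[s:e] >= min_cov).sum()) for s, e in cds)
        if covered / total >= min_frac:
            out.add(gene)
    return out


def flag_intergenic(
    interval: tuple[str, int, int],
    annotation: GeneAnnotation,
    min_dist: int = 1000,
) -> bool:
    """True when the span is at least ``min_dist`` bp from every gene span
    (strand-ignoring) on its contig."""
    contig, start, end = interval
    for gene in annotation.genes:
        g_contig, g_start, g_end = annotation.gene_span(gene)
        if g_contig != contig:
            continue
        if start < g_end and g_start < end:
            return False  # overlap
        dist = g_start - end if g_start >= end else start - g_end
        if dist < min_dist:
            return False
    return True


def differences_table(diffs: list[BreedDifference], breeds: list[str]) -> pd.DataFrame:
    """Differences as a flat TSV-ready table (1-based ``pos``)."""
    rows = []
    for d in diffs:
        row = {"contig": d.contig, "pos": d.position + 1}
        for b in breeds:
            row[f"consensus_{b}"] = d.breed_consensus.get(b)
        row.update(
            {
                "differing_pairs": ";".join(
                    f"{a}|{b}" for a, b in sorted(d.differing_pairs)
                ),
                "region": d.region,
                "effect": d.effect,
                "gene": d.gene or ".",
                "codon_ref": d.codon_ref or ".",
                "codon_alt": d.codon_alt or ".",
                "aa_ref": d.aa_ref or ".",
                "aa_alt": d.aa_alt or ".",
            }
        )
        rows.append(row)
    cols = (
        ["contig", "pos"] + [f"consensus_{b}" for b in breeds]
        + ["differing_pairs", "region", "effect", "gene",
           "codon_ref", "codon_alt", "aa_ref", "aa_alt"]
    )
    return pd.DataFrame(rows, columns=cols)
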