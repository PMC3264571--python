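"""Fragment-to-isoform assignment, abundance (FPKM), and DE calls.

Fragments are assigned to the set of isoforms they are compatible
with (every aligned block inside the isoform's exons, every used
splice junction an exon-exon junction of that isoform). A per-gene
multinomial EM splits ambiguous classes into expected isoform counts;
FPKM_i = count_i / (l_i/1e3 * N/1e6) with l_i the isoform's exonic
length and N the library's mapped fragments. Between-library scaling
uses upper-quartile normalization (75th percentile of nonzero gene
counts). Differential expression uses a two-sided likelihood-ratio
test of equal Poisson rates with library-size offsets — a deliberate,
replicate-free simplification, since each breed pool is one library —
with Benjamini-Hochberg FDR control; a gene is called significant at
|log2FC| >= 1 and q < 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GeneAnnotation, TranscriptModel

log = logging.getLogger(__name__)


@dataclass
class CompatibilityCounts:
    """Per-gene equivalence classes of fragments plus the library size."""

    breed: str
    classes: dict[str, dict[frozenset, int]] = field(default_factory=dict)
    library_size: int = 0  # total mapped fragments
    n_unassigned: int = 0  # mapped fragments compatible with no isoform

    def gene_total(self, gene: str) -> int:
        return sum(self.classes.get(gene, {}).values())


def _fragment_blocks_and_junctions(mates) -> tuple[list[tuple[int, int]], set]:
    """Merged genomic blocks of both mates and the splice junctions used."""
    blocks: list[tuple[int, int]] = []
    junctions: set[tuple[int, int]] = set()
    for read in mates:
        rb = read.get_blocks()
        blocks.extend(rb)
        for (s1, e1), (s2, e2) in zip(rb, rb[1:]):
            if s2 > e1:  # N gap
                junctions.add((e1, s2))
    merged: list[tuple[int, int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged, junctions


def _compatible(blocks, junctions, tx: TranscriptModel) -> bool:
    for s, e in blocks:
        if not any(xs <= s and e <= xe for xs, xe in tx.exons):
            return False
    return junctions <= tx.junctions


def count_compatible_fragments(
    sam_path, annotation: GeneAnnotation, breed: str | None = None
) -> CompatibilityCounts:
    """Build per-gene fragment equivalence classes from a SAM stream."""
    import pysam

    from .pileup import _usable

    sam_path = str(sam_path)
    breed = breed or sam_path.rsplit("/", 1)[-1].removesuffix(".sam")
    by_gene_span: dict[str, list[tuple[int, int, str]]] = {}
    for gene in annotation.genes:
        contig, s, e = annotation.gene_span(gene)
        by_gene_span.setdefault(contig, []).append((s, e, gene))

    fragments: dict[str, list] = {}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for read in sam:
            if not _usable(read):
                continue
            fragments.setdefault(read.query_name, []).append(read)

    counts = CompatibilityCounts(breed=breed)
    counts.library_size = len(fragments)
    for name, mates in fragments.items():
        if len(mates) == 1:
            log.debug("orphan mate %s counted as single-end evidence", name)
        contig = mates[0].reference_name
        blocks, junctions = _fragment_blocks_and_junctions(mates)
        lo, hi = blocks[0][0], blocks[-1][1]
        compatible: set[tuple[str, str]] = set()
        for s, e, gene in by_gene_span.get(contig, []):
            if s < hi and lo < e:
                for tx in annotation.transcripts_of(gene):
                    if _compatible(blocks, junctions, tx):
                        compatible.add((gene, tx.transcript_id))
        if not compatible:
            counts.n_unassigned += 1
            continue
        genes = {g for g, _ in compatible}
        if len(genes) > 1:  # ambiguous between genes: rare; skip from gene classes
            counts.n_unassigned += 1
            continue
        gene = genes.pop()
        key = frozenset(t for _, t in compatible)
        counts.classes.setdefault(gene, {})[key] = (
            counts.classes.setdefault(gene, {}).get(key, 0) + 1
        )
    return counts


def em_gene(
    classes: dict[frozenset, int],
    isoforms: list[str],
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[np.ndarray, list[float]]:
    """EM for one gene's isoform fragment shares.

    Returns expected fragment counts per isoform (in ``isoforms``
    order) and the log-likelihood trace (one entry per iteration,
    non-decreasing).
    """
    k = len(isoforms)
    index = {t: i for i, t in enumerate(isoforms)}
    total = sum(classes.values())
    if total == 0:
        return np.zeros(k), []
    masks = []
    ns = []
    for key, n in classes.items():
        m = np.zeros(k, dtype=bool)
        for t in key:
            m[index[t]] = True
        masks.append(m)
        ns.append(n)
    ns_arr = np.array(ns, dtype=float)
    mask_arr = np.array(masks)
    alpha = np.full(k, 1.0 / k)
    ll_trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        class_prob = mask_arr @ alpha  # P(fragment in class)
        ll = float(np.sum(ns_arr * np.log(np.maximum(class_prob, 1e-300))))
        ll_trace.append(ll)
        # E: split each class count among its isoforms by current alpha
        with np.errstate(invalid="ignore"):
            resp = mask_arr * alpha / class_prob[:, None]
        resp = np.nan_to_num(resp)
        counts = resp.T @ ns_arr
        new_alpha = counts / total
        if abs(ll - prev_ll) <= tol * max(1.0, abs(ll)):
            alpha = new_alpha
            break
        alpha = new_alpha
        prev_ll = ll
    return alpha * total, ll_trace


def em_isoform_abundance(
    compat: CompatibilityCounts,
    annotation: GeneAnnotation,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Expected counts and FPKM per isoform (and summed per gene).

    Returns a table with one row per isoform: gene, transcript,
    expected_count, effective_length, fpkm, gene_fpkm.
    """
    N = max(compat.library_size, 1)
    rows = []
    for gene, tids in annotation.genes.items():
        lengths = {t: annotation.transcripts[t].length for t in tids}
        classes = compat.classes.get(gene, {})
        counts, _ = em_gene(classes, list(tids), max_iter=max_iter, tol=tol)
        for t, c in zip(tids, counts):
            fpkm = c / (lengths[t] / 1e3 * N / 1e6) if lengths[t] > 0 else 0.0
            rows.append(
                {"breed": compat.breed, "gene": gene, "transcript": t,
                 "expected_count": float(c), "effective_length": lengths[t],
                 "fpkm": fpkm}
            )
    table = pd.DataFrame(
        rows, columns=["breed", "gene", "transcript", "expected_count",
                       "effective_length", "fpkm"],
    )
    gene_fpkm = table.groupby("gene")["fpkm"].transform("sum")
    table["gene_fpkm"] = gene_fpkm
    return table


def gene_counts(abundance: pd.DataFrame) -> pd.Series:
    """Expected fragment counts summed to genes, indexed by gene id."""
    return abundance.groupby("gene")["expected_count"].sum()


def upper_quartile_normalize(
    counts: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale a gene-by-breed count matrix by upper quartiles.

    The per-breed scale is the 75th percentile (linear interpolation)
    of that breed's *nonzero* gene counts; normalized values are
    count / scale * geometric-mean(scales), so identical libraries pass
    through unchanged.
    """
    scales = {}
    for col in counts.columns:
        nonzero = counts[col][counts[col] > 0].to_numpy()
        if nonzero.size == 0:
            raise ValueError(f"column {col!r} has no nonzero counts")
        scales[col] = float(np.percentile(nonzero, 75, method="linear"))
    scales = pd.Series(scales)
    geo = float(np.exp(np.mean(np.log(scales))))
    normalized = counts / scales * geo
    return normalized, scales


def poisson_lrt(count_a: float, count_b: float, n_a: float, n_b: float) -> float:
    """Two-sided p for equal Poisson rates with offsets n_a, n_b."""
    if count_a < 0 or count_b < 0 or n_a <= 0 or n_b <= 0:
        raise ValueError("counts must be >= 0 and library sizes > 0")
    if count_a + count_b == 0:
        return 1.0
    rate0 = (count_a + count_b) / (n_a + n_b)
    ll = 0.0
    for c, n in ((count_a, n_a), (count_b, n_b)):
        if c > 0:
            ll += c * math.log(c / (n * rate0))
    stat = 2.0 * ll
    return float(stats.chi2.sf(stat, df=1))


def log2_fold_change(count_a: float, count_b: float, n_a: float, n_b: float) -> float:
    """log2((b/n_b)/(a/n_a)); a 0.5-fragment pseudocount guards zeros
    (display only — the test uses raw counts)."""
    if count_a == 0 and count_b == 0:
        return 0.0
    a = count_a if count_a > 0 and count_b > 0 else count_a + 0.5
    b = count_b if count_a > 0 and count_b > 0 else count_b + 0.5
    return math.log2((b / n_b) / (a / n_a))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    counts_a: pd.Series,
    counts_b: pd.Series,
    n_a: float,
    n_b: float,
    min_fold: float = 2.0,
    max_q: float = 0.05,
) -> pd.DataFrame:
    """Per-gene DE table between two libraries.

    ``counts_a``/``counts_b`` are gene-indexed fragment counts on one
    gene universe. Significance requires |log2FC| >= log2(min_fold)
    and q < max_q.
    """
    genes = counts_a.index
    counts_b = counts_b.reindex(genes).fillna(0.0)
    lfc = np.array(
        [log2_fold_change(a, b, n_a, n_b) for a, b in zip(counts_a, counts_b)]
    )
    p = np.array([poisson_lrt(a, b, n_a, n_b) for a, b in zip(counts_a, counts_b)])
    q = bh_fdr(p)
    out = pd.DataFrame(
        {"gene": genes, "count_a": counts_a.to_numpy(),
         "count_b": counts_b.to_numpy(), "log2fc": lfc, "p": p, "q": q}
    )
    out["significant"] = (np.abs(out["log2fc"]) >= math.log2(min_fold)) & (
        out["q"] < max_q
    )
    return out


def detect_breed_specific(
    gene_fpkm: pd.DataFrame, detect_threshold: float = 0.0
) -> dict[str, dict[str, set]]:
    """Detected and breed-specific gene sets per breed.

    ``gene_fpkm`` is gene-by-breed. A gene is detected where FPKM >
    ``detect_threshold`` and breed-specific when detected in exactly
    one breed.
    """
    detected = {
        breed: set(gene_fpkm.index[gene_fpkm[breed] > detect_threshold])
        for breed in gene_fpkm.columns
    }
    n_detected_in = pd.DataFrame(
        {b: gene_fpkm[b] > detect_threshold for b in gene_fpkm.columns}
    ).sum(axis=1)
    only_one = set(n_detected_in.index[n_detected_in == 1])
    return {
        breed: {"detected": detected[breed], "specific": detected[breed] & only_one}
        for breed in gene_fpkm.columns
    }
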