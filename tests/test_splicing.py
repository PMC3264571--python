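"""Splice-event classification and the √JSD usage test."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

from breedtx.genome import GeneAnnotation, TranscriptModel
from breedtx.splicing import (
    ALT_3SS,
    ALT_5SS,
    ALT_LAST_EXON,
    EXON_SKIPPING,
    INTRON_RETENTION,
    MUTUALLY_EXCLUSIVE,
    classify_events,
    diff_splicing_test,
    diff_splicing_screen,
    single_tss_multi_isoform,
    sqrt_jsd,
)


def gene_of(exons_a, exons_b, strand="+", contig_len=100000):
    ann = GeneAnnotation(contig_lengths={"c": contig_len})
    ann.add(TranscriptModel("tA", "g", "c", strand, tuple(exons_a)))
    ann.add(TranscriptModel("tB", "g", "c", strand, tuple(exons_b)))
    return ann


def events_of(ann, **kw):
    return {(e.category, e.coordinates) for e in classify_events(ann, "g", **kw)}


class TestSingleTss:
    def test_shared_tss_two_isoforms_selected(self):
        ann = gene_of([(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)])
        assert single_tss_multi_isoform(ann) == {"g": ["tA", "tB"]}

    def test_one_bp_tss_shift_excluded(self):
        ann = gene_of([(0, 100), (200, 300)], [(1, 100), (200, 300)])
        assert single_tss_multi_isoform(ann) == {}

    def test_single_isoform_excluded(self):
        ann = GeneAnnotation(contig_lengths={"c": 1000})
        ann.add(TranscriptModel("t", "g", "c", "+", ((0, 100),)))
        assert single_tss_multi_isoform(ann) == {}

    def test_minus_strand_tss_is_three_prime_end(self):
        # shared genomic end on '-' = shared TSS despite different first exons
        ann = gene_of([(0, 100), (400, 500)], [(50, 100), (400, 500)], strand="-")
        assert "g" in single_tss_multi_isoform(ann)


class TestEventExamples:
    def test_exon_skipping(self):
        ann = gene_of([(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)])
        assert events_of(ann) == {(EXON_SKIPPING, ((200, 300),))}

    def test_alt_5ss_plus_strand(self):
        ann = gene_of([(0, 100), (200, 300)], [(0, 120), (200, 300)])
        assert events_of(ann) == {(ALT_5SS, ((100, 120),))}

    def test_alt_5ss_flips_to_alt_3ss_on_minus(self):
        ann = gene_of([(0, 100), (200, 300)], [(0, 120), (200, 300)], strand="-")
        assert events_of(ann) == {(ALT_3SS, ((100, 120),))}

    def test_intron_retention(self):
        ann = gene_of([(0, 100), (200, 300)], [(0, 300)])
        assert events_of(ann) == {(INTRON_RETENTION, ((100, 200),))}

    def test_mutually_exclusive(self):
        a = [(0, 100), (200, 300), (500, 600)]
        b = [(0, 100), (350, 450), (500, 600)]
        ann = gene_of(a, b)
        assert events_of(ann) == {(MUTUALLY_EXCLUSIVE, ((200, 300), (350, 450)))}

    def test_alt_last_exon(self):
        a = [(0, 100), (200, 300)]
        b = [(0, 100), (400, 500)]
        ann = gene_of(a, b)
        assert events_of(ann) == {(ALT_LAST_EXON, ((200, 300), (400, 500)))}

    def test_alt_first_exon_suppressed_by_default(self):
        a = [(0, 100), (400, 500)]
        b = [(200, 300), (400, 500)]
        ann = gene_of(a, b)
        assert events_of(ann) == set()
        assert events_of(ann, include_alt_first_exon=True) == {
            ("alt_first_exon", ((0, 100), (200, 300)))
        }

    def test_events_deduplicated_across_pairs(self):
        ann = GeneAnnotation(contig_lengths={"c": 1000})
        ann.add(TranscriptModel("t1", "g", "c", "+", ((0, 100), (200, 300), (400, 500))))
        ann.add(TranscriptModel("t2", "g", "c", "+", ((0, 100), (400, 500))))
        ann.add(TranscriptModel("t3", "g", "c", "+",
                                ((0, 100), (200, 300), (400, 500), (600, 700))))
        events = classify_events(ann, "g")
        skip_events = [e for e in events if e.category == EXON_SKIPPING]
        assert len(skip_events) == 1  # t1/t2 and t3/t2 describe the same skipping


# ----------------------------------------------------------------------
# independent interval-rule oracle on random two-isoform genes
# ----------------------------------------------------------------------

def oracle_events(exons_a, exons_b, strand):
    """Brute-force restatement of the six classification rules."""
    def introns(exons):
        return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]

    ia, ib = introns(exons_a), introns(exons_b)
    out = set()

    # mutually exclusive middle exons between shared flanks
    mx_members = set()
    for i in range(1, len(exons_a) - 1):
        for j in range(1, len(exons_b) - 1):
            ea, eb = exons_a[i], exons_b[j]
            same_flanks = (
                exons_a[i - 1][1] == exons_b[j - 1][1]
                and exons_a[i + 1][0] == exons_b[j + 1][0]
            )
            disjoint = ea[1] <= eb[0] or eb[1] <= ea[0]
            neither_shared = ea not in exons_b and eb not in exons_a
            if same_flanks and disjoint and ea != eb and neither_shared:
                out.add((MUTUALLY_EXCLUSIVE, tuple(sorted((ea, eb)))))
                mx_members.update({ea, eb})

    for exons_x, introns_y in ((exons_a, ib), (exons_b, ia)):
        for i in range(1, len(exons_x) - 1):
            bridge = (exons_x[i - 1][1], exons_x[i + 1][0])
            if bridge in introns_y and exons_x[i] not in mx_members:
                out.add((EXON_SKIPPING, (exons_x[i],)))

    for introns_x, exons_y in ((ia, exons_b), (ib, exons_a)):
        for intr in introns_x:
            if intr in (ia if exons_y is exons_a else ib):
                continue
            if any(s <= intr[0] and intr[1] <= e for s, e in exons_y):
                out.add((INTRON_RETENTION, (intr,)))

    only_a = [i for i in ia if i not in ib]
    only_b = [i for i in ib if i not in ia]
    for (sa, ea), (sb, eb) in itertools.product(only_a, only_b):
        if ea == eb and sa != sb:
            region = (min(sa, sb), max(sa, sb))
            longer_exon_side = exons_a if sa > sb else exons_b
            if any(s <= region[0] and region[1] <= e for s, e in longer_exon_side):
                out.add((ALT_5SS if strand == "+" else ALT_3SS, (region,)))
        if sa == sb and ea != eb:
            region = (min(ea, eb), max(ea, eb))
            longer_exon_side = exons_a if ea < eb else exons_b
            if any(s <= region[0] and region[1] <= e for s, e in longer_exon_side):
                out.add((ALT_3SS if strand == "+" else ALT_5SS, (region,)))

    # alternative terminal exons (non-overlapping, shared flanking junction)
    if len(exons_a) > 1 and len(exons_b) > 1:
        for genomic_last in (True, False):
            if genomic_last:
                intr_a, intr_b = ia[-1], ib[-1]
                term_a, term_b = exons_a[-1], exons_b[-1]
                shared = intr_a[0] == intr_b[0]
            else:
                intr_a, intr_b = ia[0], ib[0]
                term_a, term_b = exons_a[0], exons_b[0]
                shared = intr_a[1] == intr_b[1]
            disjoint = term_a[1] <= term_b[0] or term_b[1] <= term_a[0]
            if shared and intr_a != intr_b and disjoint:
                transcript_last = genomic_last if strand == "+" else not genomic_last
                category = ALT_LAST_EXON if transcript_last else "alt_first_exon"
                out.add((category, tuple(sorted((term_a, term_b)))))
    return out


def random_two_isoform_gene(rng):
    """Isoform B derives from A by one structural edit; shared TSS."""
    n_ex = int(rng.integers(3, 6))
    exons = []
    pos = int(rng.integers(0, 50))
    for _ in range(n_ex):
        length = int(rng.integers(80, 200))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(150, 400))
    strand = "+" if rng.random() < 0.5 else "-"
    edit = rng.choice(
        ["skip", "donor", "acceptor", "retain", "mutex", "terminal"]
    )
    b = list(exons)
    if edit == "skip":
        k = int(rng.integers(1, n_ex - 1))
        b.pop(k)
    elif edit == "donor":
        k = int(rng.integers(0, n_ex - 1))
        s, e = b[k]
        delta = int(rng.integers(10, 80))
        b[k] = (s, e + delta)  # extend into the intron
    elif edit == "acceptor":
        k = int(rng.integers(1, n_ex))
        s, e = b[k]
        delta = int(rng.integers(10, 80))
        b[k] = (s - delta, e)
    elif edit == "retain":
        k = int(rng.integers(0, n_ex - 1))
        b[k] = (b[k][0], b[k + 1][1])
        b.pop(k + 1)
    elif edit == "mutex":
        k = int(rng.integers(1, n_ex - 1))
        lo, hi = exons[k - 1][1], exons[k + 1][0]
        width = int(rng.integers(30, 60))
        if exons[k][0] - lo >= width + 20:
            b[k] = (lo + 10, lo + 10 + width)
        elif hi - exons[k][1] >= width + 20:
            b[k] = (hi - 10 - width, hi - 10)
        else:
            b.pop(k)  # no room: degrade to a skip
    else:  # terminal exon replacement at the transcript 3' end
        if strand == "+":
            s, e = b[-1]
            gap = int(rng.integers(50, 120))
            b[-1] = (e + gap, e + gap + int(rng.integers(80, 150)))
        else:
            s, e = b[0]
            gap = int(rng.integers(20, min(s - 1, 120))) if s > 40 else 0
            if gap:
                b[0] = (max(0, s - gap - 60), s - gap)
            else:
                b.pop(1)
    return tuple(exons), tuple(sorted(b)), strand


def test_classifier_matches_interval_oracle():
    rng = np.random.default_rng(2024)
    n_checked = 0
    for _ in range(500):
        exons_a, exons_b, strand = random_two_isoform_gene(rng)
        if exons_a == exons_b:
            continue
        ann = gene_of(exons_a, exons_b, strand=strand)
        got = events_of(ann, include_alt_first_exon=True)
        expect = oracle_events(list(exons_a), list(exons_b), strand)
        assert got == expect, (exons_a, exons_b, strand)
        n_checked += 1
    assert n_checked >= 490


def test_strand_covariance_of_categories():
    """A pure strand flip swaps donor/acceptor (and terminal-exon)
    categories; reflecting coordinates *and* flipping strand describes
    the same molecule, so every category is preserved."""
    rng = np.random.default_rng(7)
    L = 100000
    swap = {ALT_5SS: ALT_3SS, ALT_3SS: ALT_5SS,
            ALT_LAST_EXON: "alt_first_exon", "alt_first_exon": ALT_LAST_EXON}
    for _ in range(120):
        exons_a, exons_b, strand = random_two_isoform_gene(rng)
        ann = gene_of(exons_a, exons_b, strand=strand)
        fwd = events_of(ann, include_alt_first_exon=True)

        flipped = "-" if strand == "+" else "+"
        ann_f = gene_of(exons_a, exons_b, strand=flipped)
        assert events_of(ann_f, include_alt_first_exon=True) == {
            (swap.get(cat, cat), coords) for cat, coords in fwd
        }

        def reflect(exons):
            return tuple(sorted((L - e, L - s) for s, e in exons))

        ann_r = gene_of(reflect(exons_a), reflect(exons_b), strand=flipped)
        rev = events_of(ann_r, include_alt_first_exon=True)
        assert rev == {
            (cat, tuple(sorted((L - e, L - s) for s, e in coords)))
            for cat, coords in fwd
        }


class TestSqrtJsd:
    def test_identity_is_zero(self):
        assert sqrt_jsd([0.4, 0.6], [0.4, 0.6]) == 0.0

    def test_disjoint_is_one(self):
        assert sqrt_jsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_quarter_three_quarter_closed_form(self):
        assert sqrt_jsd([0.75, 0.25], [0.25, 0.75]) == pytest.approx(0.43442, abs=5e-6)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            p = rng.dirichlet(np.ones(k))
            q = rng.dirichlet(np.ones(k))
            assert sqrt_jsd(p, q) == pytest.approx(
                float(jensenshannon(p, q, base=2)), abs=1e-9
            )

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            p, q, r = rng.dirichlet(np.ones(3), size=3)
            d_pq, d_qr, d_pr = sqrt_jsd(p, q), sqrt_jsd(q, r), sqrt_jsd(p, r)
            assert 0.0 <= d_pq <= 1.0
            assert d_pq == pytest.approx(sqrt_jsd(q, p))
            assert d_pr <= d_pq + d_qr + 1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sqrt_jsd([1.0], [0.5, 0.5])


class TestDiffSplicingTest:
    def test_identical_counts_null(self):
        obs, p = diff_splicing_test([50, 50], [50, 50], n_boot=200, seed=0)
        assert obs == 0.0 and p == 1.0

    def test_disjoint_counts_extreme(self):
        obs, p = diff_splicing_test([100, 0], [0, 100], n_boot=999, seed=0)
        assert obs == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_zero_breed_untestable(self):
        with pytest.raises(ValueError):
            diff_splicing_test([0, 0], [10, 10], n_boot=10, seed=0)

    def test_screen_excludes_untestable_from_fdr(self):
        screen = diff_splicing_screen(
            {"good": (np.array([30, 70]), np.array([60, 40])),
             "bad": (np.array([0, 0]), np.array([10, 10]))},
            n_boot=200, seed=1,
        )
        bad = screen[screen.gene == "bad"].iloc[0]
        assert not bad.testable and np.isnan(bad.q)
        good = screen[screen.gene == "good"].iloc[0]
        assert good.testable and 0 < good.p <= 1 and good.q == good.p
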