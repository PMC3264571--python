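"""Cross-breed fixed differences and coding-effect annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from breedtx.divergence import (
    BreedDifference,
    EffectAnnotator,
    classify_codon_change,
    cross_breed_differences,
    flag_intergenic,
    genes_with_cds_coverage,
    genes_with_nonsynonymous,
)
from breedtx.genome import GeneAnnotation, TranscriptModel, revcomp
from breedtx.pileup import AlleleCountTable

# hard-coded standard genetic code: the independent oracle
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

ALL_CODONS = sorted(GENETIC_CODE)


def _oracle_effect(ref_codon, alt_codon):
    aa_ref, aa_alt = GENETIC_CODE[ref_codon], GENETIC_CODE[alt_codon]
    if aa_alt == "*" and aa_ref != "*":
        return "stop_gained"
    if aa_ref == "*" and aa_alt != "*":
        return "stop_lost"
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def _calls(breed, sites):
    """Site-call frame from {position: (status, consensus)}."""
    return pd.DataFrame(
        [
            {"breed": breed, "contig": "c", "position": pos, "status": status,
             "consensus": consensus, "depth": 20}
            for pos, (status, consensus) in sites.items()
        ]
    )


class TestCrossBreedDifferences:
    def test_identical_consensus_yields_no_difference(self):
        calls = {
            b: _calls(b, {5: ("monomorphic", "A")}) for b in ("x", "y", "z")
        }
        diffs, pair_counts, n_det = cross_breed_differences(calls)
        assert diffs == [] and n_det == 1
        assert all(v == 0 for v in pair_counts.values())

    def test_differing_pairs_enumerated(self):
        calls = {
            "x": _calls("x", {5: ("monomorphic", "A")}),
            "y": _calls("y", {5: ("monomorphic", "G")}),
            "z": _calls("z", {5: ("monomorphic", "A")}),
        }
        diffs, pair_counts, n_det = cross_breed_differences(calls)
        assert n_det == 1 and len(diffs) == 1
        assert diffs[0].differing_pairs == frozenset({("x", "y"), ("y", "z")})
        assert pair_counts == {("x", "y"): 1, ("x", "z"): 0, ("y", "z"): 1}

    def test_polymorphic_breed_excludes_site(self):
        calls = {
            "x": _calls("x", {5: ("polymorphic", None)}),
            "y": _calls("y", {5: ("monomorphic", "G")}),
            "z": _calls("z", {5: ("monomorphic", "G")}),
        }
        _, _, n_det = cross_breed_differences(calls)
        assert n_det == 0

    def test_breed_label_permutation_symmetry(self):
        sites = {
            p: ("monomorphic", np.random.default_rng(p).choice(list("ACGT")))
            for p in range(40)
        }
        calls = {
            "x": _calls("x", sites),
            "y": _calls("y", {p: ("monomorphic", "A") for p in range(40)}),
        }
        _, counts_xy, _ = cross_breed_differences(calls)
        _, counts_yx, _ = cross_breed_differences(
            {"y": calls["y"], "x": calls["x"]}
        )
        assert counts_xy[("x", "y")] == counts_yx[("y", "x")]


def _codon_annotation(strand):
    """One transcript whose CDS is all 64 codons in order."""
    tx_seq = "".join(ALL_CODONS)
    if strand == "+":
        contig_seq = tx_seq
    else:
        contig_seq = revcomp(tx_seq)
    n = len(tx_seq)
    ann = GeneAnnotation(contig_lengths={"c": n})
    ann.add(TranscriptModel("t1", "g1", "c", strand, ((0, n),), ((0, n),)))
    return ann, {"c": contig_seq}


@pytest.mark.parametrize("strand", ["+", "-"])
def test_effect_annotation_matches_codon_oracle(strand):
    """All 64 codons x 9 substitutions against the hard-coded code table."""
    ann, ref = _codon_annotation(strand)
    annotator = EffectAnnotator(ann, ref)
    tx = ann.transcripts["t1"]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n_cases = 0
    for ci, codon in enumerate(ALL_CODONS):
        for off in range(3):
            for alt_t in "ACGT":
                if alt_t == codon[off]:
                    continue
                tpos = 3 * ci + off
                gpos = tx.transcript_to_genome(tpos)
                alt_g = alt_t if strand == "+" else comp[alt_t]
                ref_g = ref["c"][gpos]
                diff = BreedDifference(
                    contig="c", position=gpos,
                    breed_consensus={"x": ref_g, "y": alt_g},
                    differing_pairs=frozenset({("x", "y")}),
                )
                out = annotator.annotate(diff)
                alt_codon = codon[:off] + alt_t + codon[off + 1 :]
                assert out.region == "CDS"
                assert out.codon_ref == codon and out.codon_alt == alt_codon
                assert out.effect == _oracle_effect(codon, alt_codon), (codon, alt_codon)
                n_cases += 1
    assert n_cases == 576


class TestEffectExamples:
    def test_synonymous_third_position(self):
        assert classify_codon_change("GAA", "GAG") == "synonymous"

    def test_nonsynonymous_first_position(self):
        assert classify_codon_change("AAA", "GAA") == "nonsynonymous"

    def test_minus_strand_stop_gain_via_genome(self):
        """Genomic change on '-' producing TGG->TGA on the transcript."""
        tx_seq = "ATG" + "TGG" + "TAA"
        contig = revcomp(tx_seq)
        ann = GeneAnnotation(contig_lengths={"c": 9})
        ann.add(TranscriptModel("t", "g", "c", "-", ((0, 9),), ((0, 9),)))
        annotator = EffectAnnotator(ann, {"c": contig})
        tx = ann.transcripts["t"]
        gpos = tx.transcript_to_genome(5)  # third base of TGG
        diff = BreedDifference(
            contig="c", position=gpos,
            breed_consensus={"x": contig[gpos], "y": "T"},  # G->A on transcript
            differing_pairs=frozenset({("x", "y")}),
        )
        out = annotator.annotate(diff)
        assert (out.codon_ref, out.codon_alt, out.effect) == ("TGG", "TGA", "stop_gained")

    def test_exonic_noncoding_and_other_regions(self):
        ann = GeneAnnotation(contig_lengths={"c": 100})
        ann.add(TranscriptModel("t", "g", "c", "+", ((10, 40),), ((16, 34),)))
        annotator = EffectAnnotator(ann, {"c": "A" * 100})
        base = dict(
            breed_consensus={"x": "A", "y": "C"},
            differing_pairs=frozenset({("x", "y")}),
        )
        exonic = annotator.annotate(BreedDifference(contig="c", position=12, **base))
        assert (exonic.region, exonic.effect) == ("exonic_noncoding", "none")
        other = annotator.annotate(BreedDifference(contig="c", position=60, **base))
        assert (other.region, other.effect) == ("other", "none")

    def test_position_outside_contig_raises(self):
        ann = GeneAnnotation(contig_lengths={"c": 100})
        ann.add(TranscriptModel("t", "g", "c", "+", ((10, 40),)))
        annotator = EffectAnnotator(ann, {"c": "A" * 100})
        with pytest.raises(IndexError):
            annotator.locate("c", 500)

    def test_nonsynonymous_gene_tally_counts_distinct_genes(self):
        diffs = [
            BreedDifference("c", 1, {"x": "A", "y": "C"}, frozenset({("x", "y")}),
                            region="CDS", effect="nonsynonymous", gene="g1"),
            BreedDifference("c", 2, {"x": "A", "y": "C"}, frozenset({("x", "y")}),
                            region="CDS", effect="stop_gained", gene="g1"),
            BreedDifference("c", 3, {"x": "A", "y": "C"}, frozenset({("x", "y")}),
                            region="CDS", effect="synonymous", gene="g2"),
        ]
        assert genes_with_nonsynonymous(diffs) == {"g1"}


class TestCdsCoverageFilter:
    def _annotation(self):
        ann = GeneAnnotation(contig_lengths={"c": 1000})
        ann.add(TranscriptModel("t", "g", "c", "+", ((100, 400),), ((100, 400),)))
        return ann

    def _table(self, covered_bases, depth=12):
        table = AlleleCountTable("b", {"c": 1000})
        for pos in covered_bases:
            table.counts["c"][pos, 0, 0] = depth
        return table

    def test_exactly_half_covered_included(self):
        ann = self._annotation()
        table = self._table(range(100, 250))  # 150 of 300 bases
        assert genes_with_cds_coverage(ann, table) == {"g"}

    def test_just_below_half_excluded(self):
        ann = self._annotation()
        table = self._table(range(100, 249))  # 149 bases
        assert genes_with_cds_coverage(ann, table) == set()

    def test_depth_below_ten_does_not_count(self):
        ann = self._annotation()
        table = self._table(range(100, 400), depth=9)
        assert genes_with_cds_coverage(ann, table) == set()

    def test_uniform_coverage_includes_all_cds_genes(self, small_dataset):
        from breedtx.pileup import build_pileup

        table = build_pileup(small_dataset.sam_paths["breed1"])
        ann = small_dataset.annotation
        cds_genes = {g for g in ann.genes if ann.gene_cds_union(g)}
        assert genes_with_cds_coverage(ann, table) == cds_genes


class TestIntergenicFlag:
    def _annotation(self):
        ann = GeneAnnotation(contig_lengths={"c": 100000})
        ann.add(TranscriptModel("t", "g", "c", "+", ((10000, 12000),)))
        return ann

    def test_999_bp_away_is_not_intergenic(self):
        ann = self._annotation()
        assert flag_intergenic(("c", 8401, 9001), ann) is False

    def test_1000_bp_away_is_intergenic(self):
        ann = self._annotation()
        assert flag_intergenic(("c", 8400, 9000), ann) is True

    def test_overlap_is_not_intergenic(self):
        ann = self._annotation()
        assert flag_intergenic(("c", 11000, 11500), ann) is False

    def test_empty_annotation_is_intergenic(self):
        ann = GeneAnnotation(contig_lengths={"c": 1000})
        assert flag_intergenic(("c", 0, 10), ann) is True
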