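# Methods

## Setting and assumptions

Each population ("breed") is sequenced as one pooled RNA library:
many individuals' RNA mixed before library construction. A covered
base therefore yields a pool-level allele-frequency observation, not
genotypes, and the pool is modelled as a single allele-frequency
distribution per site — individual animals are not modelled. All
analyses take alignments (SAM), a reference (FASTA) and transcript
models (GTF) as given; read alignment and transcript assembly are
outside the package's scope, and novel-isoform discovery is not
attempted.

Coordinates are 0-based half-open internally; GTF is written/read
1-based inclusive and SAM positions follow the SAM convention.

## Site calling

`CallingThresholds` defaults: `min_coverage = 10` fragments,
`minor_frac = 0.10`, `min_qual = 20` (Phred), `top2_frac = 0.90`.
Depth is fragment-deduplicated (unique primary alignments, intron
skips honoured, overlapping mates merged keeping the higher-quality
base call — one molecule is never counted twice).

The polymorphic verdict follows the three pooled-SNP filters (minor
fraction, both-strand Q20 support of both top alleles, top-two
dominance). "Monomorphic" needs a positive definition to safely feed
the between-breed comparison: we require the complement of the minor
fraction criterion *plus* top-base dominance ≥ `top2_frac` *plus*
both-strand Q20 support of the top base; everything else surveyed is
"ambiguous". This prevents low-quality or three-allele sites from
producing spurious fixed differences. The quality filter applies to
base quality only; mapping uniqueness is already enforced via
`NH == 1`. Base-rank ties break by the fixed order A < C < G < T.
Fractional-threshold comparisons use an epsilon of 1e-9, which is
exact for integer counts at any realistic depth (count gaps are
≥ 1/depth); the test suite checks the caller against an
exact-rational-arithmetic restatement on an exhaustive enumeration.

## Fixed differences and coding effects

`n_determinable` counts sites monomorphic-callable in every pool; a
`BreedDifference` is a determinable site with ≥ 1 differing consensus
pair. For effect annotation, a position inside the CDS of several
transcripts is attributed to the transcript with the longest CDS
(ties by transcript id) so each site receives one deterministic
label. The codon is read in frame on the transcript strand,
the alternate allele substituted (complemented on '−'), and both
codons translated with the standard genetic code; stop_gained /
stop_lost take precedence over the synonymous/nonsynonymous split.
The gene-level coverage filter admits genes with ≥ 50% of CDS-union
bases at deduplicated fragment depth ≥ 10 (boundary inclusive), and
the intergenic flag requires ≥ 1,000 bp distance from every annotated
gene span, strand-ignoring.

## Expression

Fragment–isoform compatibility requires every aligned block inside
the isoform's exons and every CIGAR-N junction to match an isoform
junction; fragments whose compatible isoforms span multiple genes
(impossible in the simulator's non-overlapping layouts) are counted
as unassigned rather than guessed. The per-gene EM iterates fragment
shares α over isoforms: responsibilities split each equivalence class
proportionally to current α, with the log-likelihood
Σ_c n_c log Σ_{i∈c} α_i non-decreasing; termination at relative
log-likelihood change ≤ 1e-8 or 1,000 iterations. Expected counts are
conserved (Σ_i = observed fragments) by construction. FPKM uses the
isoform's exonic length; gene FPKM is the isoform sum.

Upper-quartile scales are the 75th percentile (linear interpolation,
rank 1 + 0.75(n−1)) of *nonzero* gene counts; normalized values are
rescaled by the geometric mean of scales so identical libraries pass
through unchanged.

With one library per pool there are no replicates, so a dispersion
model cannot be estimated; DE therefore uses a two-sided Poisson LRT
with library-size offsets, an honest simplification whose type-I
error is verified under its own assumptions (5% ± 1.5% on 2,000 null
genes). Fold changes displayed for zero counts add a 0.5-fragment
pseudocount; the test itself always uses raw counts. Detection for
breed-specific calls defaults to FPKM > 0 ("any evidence") and is
configurable, since any fixed threshold choice materially changes the
breed-specific sets and low-expression genes dominate them.
Sequence-bias correction is not applied; the run summary records
this.

## Splicing

The analysis keeps genes whose isoforms all share one TSS (strict
coordinate equality; on '−' the TSS is the 3′-most genomic
coordinate) and have ≥ 2 isoforms, so alternative first exons cannot
arise; the first-exon classifier exists behind a flag for
completeness. Events are classified per isoform pair from intron
chains and deduplicated by (category, sorted involved coordinates).
Alternative 5′/3′ splice-site calls additionally require the
alternative region to be exonic in the isoform with the shorter
intron — without this containment condition every exon-skipping pair
would also be miscounted as a splice-site shift. Terminal-exon events
require a shared flanking junction boundary and non-overlapping
terminal exons (overlapping ones are splice-site shifts).

Category symmetry: flipping the strand of a fixed structure swaps
donor- and acceptor-side categories (and first/last terminal-exon
events); reflecting coordinates *and* flipping strand describes the
same molecule and preserves every category. Both invariants are
tested.

Usage divergence is √JS in bits between relative-usage vectors built
from EM expected counts (using all fragments, not only unambiguous
ones). Significance: pool the two breeds' counts, draw `n_boot`
(default 10,000) pairs of multinomial samples at the original totals,
and use the add-one empirical tail p = (1 + #{null ≥ obs})/(n_boot+1);
q-values are Benjamini–Hochberg across testable genes, with zero-count
breeds flagged untestable and excluded from the correction. EM totals
are rounded to integers for the draw. Calibration (5% ± 1.6% on null
genes) and power on planted usage shifts are part of the test suite.

## Synthetic-data generator

The generator emulates the pooled study design: one contig, genes
laid left to right with 4 kb gaps; per gene 3–6 exons of 120–300 bp
with 200–500 bp introns; every primary isoform carries a clean ORF
(ATG, no internal stops, TAA), and where the ORF has ≥ 8 codons its
sixth-from-last codon is forced to TGG so one substitution can create
a premature stop truncating the final five amino acids — an
engineered analogue of a truncating breed-specific change. Half the
genes (configurable) carry a second isoform skipping one internal
exon, sharing both ends and hence the TSS.

Defaults (the package's standing study conditions): 3 breeds, 30
fixed differences in total — each altering exactly one breed's
haplotype, half inside CDS — and 30 within-breed SNPs per breed with
minor fractions (0.05, 0.08, 0.12, 0.30, 0.45). The list straddles
the 10% polymorphism filter: two classes below, one probing just
above the boundary, and two far enough above that, at the deep
calibration depth of 50 fragments, the binomial probability of an
observed minor fraction falling under the filter is negligible
(≈ 2·10⁻⁴ at 0.30) — so recovery tests measure filter logic, not
sampling luck. SNP minor alleles are drawn once per fragment (one
molecule), reproducing binomial allele-frequency noise, which a
deep-tiling calibration test checks against three-binomial-SD bands.

Fragments are ~300 bp sequenced 75 bp from both ends (fragment
footprint 150 bp in random mode), at 30× default fragment coverage
split across isoforms by per-breed usage vectors; a deterministic
tiling mode cuts each transcript into consecutive fragment windows
emitted `round(depth × usage)` times with mates partitioning the
window, giving exactly uniform fragment depth for recovery tests.
Mate orientation alternates (tiling) or is drawn fairly (random) so
every allele accrues both-strand support at depth ≥ 2. Errors
substitute uniformly among the three other bases at rate 0.001; in
"low_quality" mode error bases get Q15 (so the Q20 filter can remove
them — isolating filter logic), in "realistic" mode quality is drawn
independently of error status. Usage shifts mimic an
exon-skipping switch: multi-isoform genes use (0.9, 0.1) everywhere
except a configurable half, which switch to (0.4, 0.6) in the last
breed. Optional unannotated single-exon transcripts are placed in
gene gaps at ≥ 1,000 bp or < 1,000 bp from genes to exercise both
sides of the intergenic rule.

What the generator does *not* model — hence what green tests do not
show about real data: indels and structural variation, multi-mapping
and alignment error, PCR duplicates, GC/positional coverage bias,
overlapping genes, transcription noise between individuals within a
pool, and replicate-level biological variance. Recovery results are
therefore statements about the pipeline's correctness under its
stated model, not about sensitivity on real libraries.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale studies (tens of genes,
depth 30–50, 5–10 replicate seeds; calibration with 2,000 null DE
genes and 600–1,000 null splicing genes at n_boot = 2,000) — sizes
chosen so the whole suite completes in about a minute while keeping
binomial/bootstrap resolution comfortably finer than the tested
bands. All randomness flows from explicit integer seeds; identical
configs reproduce byte-identical SAM and table outputs. Known
limitations beyond the generator's scope: the Poisson DE test is
anti-conservative on overdispersed real replicates by construction,
the splice classifier does not emit events for isoform pairs whose
terminal structures differ on both boundaries at once (no shared
flanking junction), and multi-exon skipping is represented by its
bridging junction rather than per-exon events.
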