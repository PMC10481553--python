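# Methods

This note documents the models and procedures implemented in `mirqtl`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Read preprocessing

Reads are single-end FASTQ (Sanger Phred+33). The quality filter keeps a
read when its **mean** Phred score is ≥ 20 (inclusive); the threshold is a
read-level mean, the common trimming-tool default, since a per-base
semantics is equally defensible but harsher. Adapter removal strips the
longest read suffix that exactly matches a prefix of the configured adapter
(≥ 5 bases); untrimmed reads are flagged, not discarded. The length filter
keeps 17–30 nt inclusive. Identical sequences are collapsed into tags with
per-library counts, conserving total read number, and tags are mapped to
the genome by exact full-length string matching on both strands —
criterion 2 of the precursor filter demands exact matching anyway, so a
heuristic aligner would add failure modes without adding power;
multi-mapping tags retain all loci. All coordinates are 1-based inclusive.
U is normalized to T on input; internal sequences are DNA-alphabet.

## RNA folding engine

The default engine finds the minimum-free-energy **nested** secondary
structure by a Zuker-style dynamic program over an embedded approximate
nearest-neighbour parameter set: a 6×6 stacking table over the pairs
{AU, UA, GC, CG, GU, UG} with values in the −0.2 to −3.4 kcal/mol range,
size-dependent hairpin/bulge/internal-loop penalties with logarithmic
extrapolation, and an affine multiloop term (closing 3.4, per-branch 0.4
kcal/mol, unpaired bases free). Hairpin loops need ≥ 3 unpaired bases;
bulge/internal loops are capped at 30 total unpaired bases; dangles,
terminal-AU penalties, tetraloop bonuses and loop-asymmetry terms are
omitted. This is intentionally not the full Turner 2004 model: the goal is
a self-contained engine whose −15 kcal/mol stability threshold behaves like
the field's, and the folding contract (`fold(seq) -> structure, pair table,
MFE`) is pluggable, so a full-featured external predictor can be
substituted where the refinements matter.

Correctness of the DP is checked against an independent reference path:
`enumerate_structures` generates every nested structure of a short sequence
and `structure_energy` evaluates a structure by loop decomposition; the two
paths share only the parameter tables. The test suite verifies equality on
hundreds of random sequences up to 18 nt (beyond that enumeration is
exponential). Ties against the empty structure resolve to the empty
structure, so any returned pairing has strictly negative energy. Traceback
follows the fill order deterministically, so folding is reproducible
call-to-call. The DP kernel is compiled with numba when available (a pure
Python fallback keeps the package importable without it); a 250-nt window
folds in tens of milliseconds.

## Precursor calling

Each mapped tag nominates windows of 80/120/200/250 nt in two placements
(tag toward the window's 5′ or 3′ side, with a 30 nt margin); windows
running past a chromosome end are dropped, and minus-strand loci are
reverse-complemented before folding. The folded window is then **excised**
to the stem-loop hosting the tag: starting from the outermost base pair
touching the mature region, the helix is extended outward while each
enclosing pair has a single branch (stacks, bulges, internal loops), and
stops at a multiloop junction or the exterior loop. The criteria are
evaluated on that excised substructure as it folds in context — refolding
the excised sequence in isolation would judge a different molecule than the
one the window fold proposes, and long windows of background sequence fold
into large branched structures that are not precursors. The excised
structure's energy (the MFE used for criterion 8) is its standalone
loop-decomposition energy.

The eight criteria are applied with inclusive thresholds exactly as worded:
read count ≥ 3 (summed over libraries by default; a per-library maximum is
configurable since the original wording does not specify), exact-match
mapping (structurally true for every candidate — tags that do not map
exactly never nominate one), precursor length ≥ 60 nt, hairpin formed,
single-arm occupancy, star-strand mismatches ≤ 6, A+U 30–70%, MFE ≤ −15
kcal/mol. A "mismatch" is an unpaired mature position (or one pairing
outside the star span); G:U wobble counts as paired, matching plant miRNA
annotation practice. The star strand follows the canonical Dicer geometry:
the segment pairing the mature arm, extended by a 2-nt 3′ overhang. A
mature tag overlapping the terminal loop fails the single-arm criterion
even if well paired. The eight criteria act as the sole classifier — no
additional probabilistic scoring is layered on top.

Candidates from multiple windows of one locus are deduplicated on (chrom,
strand, mature span), keeping the lowest MFE, then the shortest precursor,
then the leftmost window — a deterministic order. Known/novel status is
exact sequence identity against the reference mature set after U/T
normalization (the matching rule of the upstream discovery tools is not
published; exact identity is the conservative choice).

## Differential expression

Counts are raw tag counts per library. Eligibility requires a summed raw
count ≥ 5 in the control libraries **and** ≥ 5 in the drought libraries of
a genotype. Replicates are pooled by summing. Per-condition size factors
come from the median-of-ratios to the row-wise geometric mean (rows
expressed in both pools); total-count scaling is kept as an alternative but
is not the default because strongly regulated miRNAs shift library totals
and would bias every null miRNA's fold change. log₂FC uses pseudocount 1.
Significance is a two-sided exact binomial test of the pooled drought count
against the size-factor-implied null proportion, BH-adjusted. This is a
deliberate, documented stand-in for a negative-binomial shrinkage model: it
has no dispersion parameter, so with replicate pools and Poisson-like noise
it is exact, while overdispersed real data would make it anti-conservative
— the DE contract here is defined by the printed selection filters
(count ≥ 5 both conditions, |log₂FC| > 1 strict), with the FDR cutoff
(default 0.05) configurable or disabled for purely fold-change-driven
selection.

## Target prediction and degradome categories

One scoring engine stands in for the plant target predictors, with the
established penalty convention: mismatch 1.0, G:U 0.5, gap 2.0, each
doubled at miRNA positions 2–13 from the 5′ end; a site is kept at total
penalty ≤ 3 (inclusive). The scan enumerates every transcript offset with
zero gaps plus every single-bulge variant on either strand (a bulge is
weighted by its miRNA position); overlapping hits deduplicate to the
best-scoring site, ungapped preferred, then leftmost. Two parameterizations
are tagged per site — the default and a stricter no-gap variant — so the
multi-tool consensus logic (Venn regions, per-tool support) is preserved
with one engine. The slice site is the transcript base paired to miRNA
position 10, a single integer coordinate (the convention picks position 10
rather than the 10–11 bond; a bulge at position 10 falls back to the
nearest paired neighbour and is flagged).

Degradome libraries are 5′-end counts per transcript position. A predicted
site's T-plot category per library: 4 if the site count is exactly 1;
otherwise 0 at the unique profile maximum, 1 at a shared maximum, 2 above
the median of nonzero positions but below the maximum, 3 for any other
nonzero count; zero count is "no hit". Categories 0–2 count as validation,
with support = number of libraries at a kept category (≥ 1 by default). The
cleavage p-value some degradome pipelines compute is omitted: the selection
contract here is category-based only.

## QTL integration and reporting

The three qDTY intervals are stored verbatim from their flanking-marker
coordinates, with the chromosome implied by the locus nomenclature. Overlap
mode defaults to any-overlap (containment is available; the original
semantics are unstated). All interval arithmetic is 1-based inclusive.
Reported percentages round half-up at the printed precision — this
reproduces the published support ratios exactly, whereas three of the eight
canopy-temperature rows appear truncated rather than rounded in print and
are therefore excluded from the exact checks. Promoter analysis takes 2 kb
upstream; motif scanning is exact IUPAC matching with overlaps allowed;
allele variants come from Needleman–Wunsch global alignment (match +1,
mismatch −1, linear gap −2, via Biopython's PairwiseAligner) with positions
reported on the first allele.

The 2^−ΔΔCt fold change reports both the raw ratio and the signed
convention (−1/FC for FC < 1) that qPCR tables print for down-regulation.
Total chlorophyll uses the standard Arnon coefficients (20.2·A645 +
8.02·A663 µg/ml), scaled by extract volume over tissue mass.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study *design* at desk scale: 3 chromosomes of
60 kb (named Chr1/Chr3/Chr12), 12 small-RNA libraries (3 genotypes ×
control/drought × 2 replicates), 9 degradome libraries, 100 gene models of
300 nt, a miRBase-like reference containing half of the planted matures,
and an inventory covering 28% of genes. The qDTY intervals are affinely
rescaled onto the synthetic chromosomes (factor = synthetic/real chromosome
length, recorded in the truth object), preserving the interval logic while
keeping coordinates small.

Planted precursors: 20 true hairpins satisfy all eight criteria; decoy
classes violate exactly one criterion each — low read count (2 reads),
59-nt precursor, loop-spanning mature, seven star mismatches, A+U ≈ 85%,
and a wobble-only stem whose MFE stays above −15 kcal/mol. Criteria 2 and 4
have no decoy class: exact mapping is structural (an unmappable tag never
yields a candidate), and a candidate that forms no hairpin necessarily also
fails the stability bound, so neither can be violated in isolation. Each
locus is insulated with ~250 nt of A/C-alphabet context (poly-A for the
weak-stem class): A and C cannot pair each other, and with the 30-nt
interior-loop cap no helix can bridge the insulation, so the planted
stem-loop is the hairpin the windows fold regardless of the random genome
beyond. Planting is self-verifying — after writing a hairpin the generator
runs the actual discovery evaluation and re-randomizes (seeded, bounded
attempts) until the criteria vector matches the designated class — and
every design pairs at least two mature bases through G:U so the mature's
reverse complement never appears verbatim in the star arm (which would
create a spurious antisense locus). Planted matures are checked unique in
the genome.

Abundances: per-library counts are Poisson around a per-miRNA baseline
drawn from 50–200 reads; 40% of miRNAs carry a planted effect of
|log₂FC| ∈ [2, 3] (random sign) multiplying the drought mean by 2^log₂FC.
Reads are the mature sequence plus the adapter as a suffix at constant high
quality; a 5% fraction of low-quality junk reads and a few length-violating
reads exercise the filters without biasing counts. Target sites are exact
reverse complements of matures embedded into transcripts (one planted site
per gene; every miRNA gets 1–2 target genes, at least one of them
QTL-resident per study); degradome peaks of height 20 are placed at the
implied slice position in a random 1–8-library support set, over a
single-count background at rate 0.005/nt, so planted peaks are unique
maxima (category 0) by construction.

Not emulated: realistic genome composition (the insulation islands are
deliberately low-complexity), sequencing errors, isomiRs, overdispersed
counts (a negative-binomial option would be the first extension),
mismatch-containing target sites, multi-exon genes, and genotype-specific
regulation (planted effects apply across genotypes). Consequently, passing
tests demonstrate that the algorithms implement their contracts and recover
a signal they can represent — not that the pipeline is robust to the noise
structure of real sequencing data. Background/noise levels are fixtures,
not estimates of any real library.

## Problem sizes and determinism

The default study (20 true + 30 decoy loci, 100 genes, 12 + 9 libraries)
generates in a few seconds and runs end-to-end in well under a minute; the
DE recovery experiment uses 100 seeded replicates of 30 miRNAs plus a
1,000-miRNA null. All randomness flows from a single integer seed through
per-stage `numpy` generators, so identical configurations produce
byte-identical outputs; folding and every selection rule break ties
deterministically.

## Known limitations

The energy model is approximate; absolute MFE values differ from Turner
2004 predictions by a few kcal/mol on typical precursors, so the −15
kcal/mol threshold is meaningful but not numerically interchangeable with
other engines' output. The exact binomial DE test is anti-conservative
under overdispersion. Exact-match mapping ignores sequencing errors by
design. The excision rule trims to a single stem-loop and will not
represent precursors whose mature spans a branched structure.
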