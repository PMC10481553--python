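# mirqtl

Drought-responsive miRNA discovery and QTL co-localization for rice
small-RNA studies.

Major rice QTLs for grain yield under drought (qDTY1.1, qDTY3.1 and
qDTY12.1) have been deployed in breeding for a decade, yet the genes
underlying them remain unresolved. One route in is regulatory: identify the
miRNAs that respond to drought stress, predict and validate their target
mRNAs, and ask which targets reside inside the QTL marker intervals.
`mirqtl` implements that integrative analysis as a tested, reusable
pipeline:

1. **Small-RNA preprocessing** — mean-quality filtering (Phred ≥ 20),
   adapter trimming, 17–30 nt length selection, collapsing identical reads
   into tags with per-library counts, and exact-match mapping of tags to
   the genome on both strands.
2. **Precursor calling** — genomic windows around each mapped tag are
   folded with a built-in minimum-free-energy engine, trimmed to the
   stem-loop hosting the tag, and passed through the eight annotation
   criteria used for plant miRNA precursors: read count ≥ 3; exact-match
   mapping; precursor ≥ 60 nt; hairpin formed; tag on a single arm; ≤ 6
   mismatches against the star strand (G:U counts as paired); A+U content
   30–70%; MFE ≤ −15 kcal/mol. Mature sequences matching a reference set
   are *known* miRNAs; the rest are *novel*, named `chr<c>_<start>`.
3. **Differential expression** — raw-count filter (≥ 5 in both control and
   drought), median-of-ratios normalization, log₂FC with pseudocount 1, a
   two-sided exact binomial test of the pooled drought count, and
   Benjamini–Hochberg FDR. A miRNA is DE when |log₂FC| > 1 (and,
   optionally, FDR ≤ α).
4. **Target prediction** — duplex complementarity scored with the plant
   convention (mismatch 1, G:U 0.5, gap 2, doubled at miRNA positions
   2–13); sites kept at penalty ≤ 3.
5. **Degradome validation** — 5′-end tag pile-ups per transcript classify
   each predicted slice site (the base paired to miRNA position 10) into
   T-plot categories 0–4; categories 0–2 count as cleavage evidence, with
   per-library support tallies.
6. **Integration** — validated targets are flagged against a
   drought-responsive gene inventory, intersected with the qDTY marker
   intervals (stored verbatim: RM212–RM12233 at 33,053,493–42,415,653 bp on
   chromosome 1, RM520–RM416 at 30,912,691–31,248,603 bp on chromosome 3,
   RM28048–RM512 at 14,106,460–17,395,485 bp on chromosome 12), summarized
   as multi-tool consensus regions and reported percentages, and exported
   as a miRNA–mRNA network (SIF/TSV). Promoter motif scanning (IUPAC) and
   pairwise allele variant calling round out locus characterization.

A first-class **synthetic-data generator** produces every input the
pipeline consumes — genome, 12 small-RNA FASTQ libraries (3 genotypes × 2
conditions × 2 replicates), gene models with embedded target sites,
degradome tag tables, a reference mature set and an inventory — with
planted ground truth, so the whole pipeline is testable offline.

## Worked example

```python
from mirqtl import SyntheticConfig, generate_dataset, run_pipeline

dataset = generate_dataset(SyntheticConfig(seed=42))
result = run_pipeline(dataset)

call = result.calls[0]
print(call.name, call.status)
print(call.precursor.structure.dot_bracket)
print(result.recovery["n_recalled"], "/", result.recovery["n_true"])
```

prints

```
chr1_1750 novel
((((((((((((((((((((((((((((((......))))))))))))))))))))))))))))))
20 / 20
```

— a novel miRNA call at Chr1:1750–1815 (66 nt precursor, MFE −57.7
kcal/mol), and full recall of the 20 planted true precursors. The same run
rejects all 30 planted decoys, each failing exactly the criterion it was
designed to violate, calls 8 of 20 miRNAs differentially expressed (the 8
with planted fold changes; e.g. `osa-synth-miR010`: control mean 415.8,
drought mean 2170.0, log₂FC +2.38, FDR ≈ 0), validates all 28 planted
(miRNA, gene, cleavage) triples at degradome category 0, and recovers
exactly the 8 validated target genes that lie inside the rescaled qDTY
intervals.

The command-line interface mirrors the stages:

```bash
mirqtl synth --out study/ --seed 42       # generate a synthetic study
mirqtl preprocess --genome study/genome.fa --adapter TGGAATTCTCGGGTGCCAAGG \
    --out work/ study/reads/*.fastq
mirqtl discover --genome study/genome.fa --tags work/tag_counts.tsv \
    --reference study/reference_mature.fa --out work/
mirqtl targets --mirnas mature.fa --transcripts study/transcripts.fa \
    --degradome study/degradome --out work/
mirqtl integrate --targets work/target_sites.tsv --gff study/genes.gff3 \
    --inventory study/inventory.tsv --out work/
mirqtl metrics --irt 31.57 34.62 --ddct 24 20 22 20
mirqtl run --out report/ --seed 42        # everything end to end
```

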