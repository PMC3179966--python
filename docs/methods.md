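# Methods

## The read-depth model

The analysis assumes shotgun reads sample the genome approximately
uniformly, so the number of read alignments whose midpoint falls in a
window of fixed *unmasked* sequence content is proportional to the copy
number of that sequence in the genome that was sequenced — not in the
assembly. A region whose two 97%-identical copies were collapsed into one
assembly locus receives the reads of both copies and shows twice the
single-copy depth. Multi-mapping alignments are therefore deliberately kept:
uniquifying reads to a best hit would erase exactly the signal being
measured.

Windows count unmasked bases only. A 1-kub window holds exactly 1,000
unmasked nucleotides plus any interposed masked ones, so its genomic span
stretches over repeat-masked sequence; a window that would cross an
assembly gap is discarded and scanning restarts at the first unmasked base
after the gap. Five contiguous 1-kub windows form a 5-kub window, sliding
by one, so neighbouring 5-kub windows share four members. Depth is the
count of filtered alignment midpoints (midpoint of a match `[s, e)` is
`s + floor((e - s - 1)/2)`; even-length matches take the left-of-centre
base — any fixed convention works, this one is stable and documented).

## Repeat masking settings

Three settings trade masking stringency against alignment behaviour:

| setting     | repeats masked                                  | mask character |
|-------------|--------------------------------------------------|---------------|
| `div10_low` | interspersed < 10% diverged + all tandem         | lowercase     |
| `nodiv_low` | all                                              | lowercase     |
| `nodiv_N`   | all                                              | N             |

Lowercase masking still allows an alignment to extend *through* a repeat
(with a < 200 bp masked-overlap cap per match); N masking truncates the
alignment at the repeat edge. The divergence filter is strict: a repeat at
exactly 10.0% divergence is not masked under `div10_low`. Both interspersed
and tandem repeats are converted to N under `nodiv_N` (the setting is a
policy change, not a repeat-class change; the alternative reading — only
tandem repeats hard-masked — is noted as open). Assembly gaps (runs of ≥ 10
N in the input) are kept on a separate track from masked repeats because
the two have opposite windowing semantics: windows extend through masked
repeats but are discarded at gaps.

The default analysis setting is `nodiv_N`: divergence-thresholded masking
leaves old, high-copy repeat subfamilies unmasked (their annotated
consensus divergence exceeds the threshold even when the copies are
mutually similar enough to cross-align), and their multi-mapping reads
masquerade as duplication signal. The package's masking-comparison fixture
reproduces this direction of effect.

## Alignment

The built-in mapper is an exact-seed (32-mer, two-bit packed, sorted-array
index), ungapped X-drop extension aligner reporting every match of ≥ 301
genomic bp at ≥ 93% identity. It never extends across an invalid character,
so N-masked repeats truncate matches. External alignments in BLAST tabular
(outfmt 6) format are accepted interchangeably; minus-strand subject
coordinates are normalised to forward half-open intervals. The original
analysis's aligner score cutoff is not reimplemented — score scales are
aligner-specific — the operative filters are match length and identity. The
aligner identity floor (93%) sits below the duplication-identity claim
(> 94%): the calibrated depth threshold, not the aligner cutoff, is what
enforces the duplication call, and substitution noise on real reads means a
94%-identical pair aligns at ~93.5%.

## Depth calibration

5-kub depths from designated single-copy calibration regions (in a real
study: loci verified single-copy by FISH; in the synthetic study: reserved
repeat-free single-copy stretches emitted by the generator) are fitted with
a constrained mixture of four Gaussians representing copy numbers 1–4:
component *n* has mean `n·avg` and standard deviation `√n·sd`, and the four
fractions sum to one. The √n scaling follows the Poisson-like growth of
count variance with the mean; a `sd_scaling="linear"` switch exposes the
alternative `n·sd` scaling. The fit minimises the unbinned −log L with
L-BFGS-B over (log avg, log sd, three fraction logits), multi-started from
the histogram mode and the sample median, with fractions initialised at
(0.85, 0.10, 0.04, 0.01) and sd at 1.4826×MAD. The contract is the
maximised likelihood, not the algorithm; EM would be an acceptable
substitute. Overlapping sliding windows enter the likelihood as if
independent — an acknowledged approximation that biases the sample size,
not the location or scale. Degenerate samples (all depths equal, or fewer
than 50 values) are rejected as fit failures. Binned normalised residuals
(pull = (N_data − N_fit)/√N_data) are reported alongside the fit for
display; bulk pulls within ±3 indicate purely statistical residuals.

Classification cuts derive from G₁: *negative* ≤ avg+2sd < *borderline* <
avg+3sd ≤ *positive*. The boundary point avg+3sd is classified positive
(the "greater than or equal" reading); a switch restores the strict
inequality.

## Interval calling

Every run of seven consecutive sliding windows containing at least six
positives marks all seven as duplicated; clusters of index-consecutive
marked windows become intervals (clusters separated by ≥ 1 unmarked window
stay separate even when their spans overlap), with mean depth over member
windows. Borderline windows neither count toward 6-of-7 nor split
intervals. No extra length filter is applied: seven 5-kub windows already
guarantee ≥ 11 kub of unmasked content, which is the ≥ 10 kb duplication
size floor by construction.

**Boundary resolution.** A called interval necessarily overshoots the
underlying copy boundary: a boundary window with only two of its five
members inside a two-copy duplication already exceeds avg+3sd at 12x, and
the 6-of-7 marking adds one more window per side, so calls extend ~3–5
unmasked kb beyond each edge before merging. On the synthetic study this
overshoot is the dominant (effectively the only) source of false-positive
bases in base-level benchmarking: measured precision is ~0.85 with
sensitivity 1.0, and >97% of false-positive bases lie within 8 kb of a true
duplication edge. Interval edges should be read with ±1 window of slack;
interval size distributions are correspondingly inflated by ~5–10 kb.

## Annotation overlays

Gene duplication status is evaluated against the union of merged intervals
(a gene spanning two abutting calls is fully duplicated). Gene density is
genes per 100 kb — over chromosome bp genome-wide, over duplicated bp for
the duplicated fraction. The domain enrichment factor for InterPro domain
*d* is the ratio of its fractional abundance among retained assignments
(status T, non-null InterPro id) of duplicated versus unique peptides;
domains absent from unique peptides are listed separately rather than given
an infinite factor. Occurrences are counted per retained match, with a
per-gene-presence switch. Organelle-derived content (NUMTs, NUPTs) is the
per-chromosome union of alignment hits at E ≤ 1e-4 — each nucleotide counted
once however many hits cover it — and, inside duplications, the intersection
of that union with called intervals, with duplicated bp as the denominator
of the inside percentage. Single-hit nucleotides count: the quantity is
genomic organelle-DNA content, not recurrence.

## The synthetic study

The generator emulates the statistical structure the analysis assumes, at
desk scale: a 5 Mb, four-sequence assembly (a main chromosome, a second
chromosome, an unplaced `_random` contig and a `chrUn` pool, so summary
strata are exercised), 20 implanted duplications of 10–100 kb at copy
number 2–4 (weights 0.6/0.3/0.1) and pairwise identity 94–99.5%, ~15%
repeat content from interspersed families (including old subfamilies with
annotated divergence 12–28% but small intra-family divergence), tandem
blocks, three assembly gaps (50/30/20 kb), 500 genes, ten organelle
insertions copied from synthetic 80 kb mitochondrial / 40 kb plastid
genomes (disjoint source slices, so insertions are single-copy), and twelve
reserved 40 kb repeat-free single-copy regions whose 2 kb-shrunken cores are
the calibration set. Reads: count = coverage × genome / mean length, uniform
starts avoiding gaps, truncated-normal lengths (mean 735, sd 130, range
300–1447), substitutions at 0.5%, and 1.26% of reads emitted with failing
trace QC so the clipping stage has work to do.

Mutation is substitution-only; each duplication copy is mutated from its
master at *half* the target divergence so the *pairwise* identity between
copies matches the requested identity. Consequences worth knowing: no
indels (the ungapped mapper and identity bookkeeping stay exact; an indel
model is a documented extension), no heterozygosity (the emulated material
is near-homozygous), no read-quality chemistry, and every copy pair of one
duplication is equidistant rather than tree-structured. Passing tests
demonstrate the pipeline's arithmetic and calling logic under the model's
assumptions; they do not demonstrate robustness to indel-rich or
tree-structured duplication families.

All randomness flows from one spec-level seed through named substreams
(genome construction, placement, reads), so each stage is independently
reproducible.

## Problem sizes and numerical choices

The bundled studies run on one CPU in minutes: the end-to-end study uses a
5 Mb genome at 12x (~82,000 reads); the mixture recovery study uses 20
samples of 5,000 draws; the masking comparison uses a 1 Mb fixture. Seeded
rather than scanned: optimizer tolerance is scipy's L-BFGS-B default;
mapper X-drop is 20 with +1/−3 match/mismatch scores (a 32-mer seed plus
stride 16 guarantees a hit inside any ≥ 301 bp error-free match segment);
interval merging treats abutting spans as contiguous; ties in the
top-duplicated-genes ranking break by (chromosome, start).
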