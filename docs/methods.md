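# Methods

## Coordinates, tracks and normalization

All coordinates are 0-based half-open (BED convention); GFF input is
converted on read. Coverage lives in fixed-width bins (default 10 bp) of
read counts plus a library size; bedGraph values are interpreted as per-base
read density, so rasterization conserves mass exactly and windowed sums with
fractional bin overlap equal a per-base computation to machine precision.
A chromosome missing from a track is treated as all-zero with a logged
warning rather than an error, so sparse toy genomes run cleanly.

Input normalization is a floored RPM ratio, not subtraction:
`S = chip_RPM / max(input_RPM, ε)` with ε = 0.5 RPM. The ratio is invariant
to rescaling a track's values and library size together, keeps signals
non-negative, and the floor prevents blow-ups over input-depleted windows.
Windows that would cross position 0 are clipped and quantified over the
remaining span without rescaling (logged).

## Enhancer discovery and classification

The TSS-distance filter uses the enhancer *summit* (maximum-signal bin of
the stimulated H3K27ac track inside the peak, ties to the left, interval
midpoint as fallback) and a strict inequality (> 1500 bp). Summit-vs-edge
anchoring is a convention choice; the summit is the stabler anchor and also
centres the quantification window and the accessibility profiles.

Classification thresholds: fold ≥ 1.5 (inclusive) for increasing, relative
reduction ≥ 33% for decreasing, |change| ≤ 10% relative to the unstimulated
signal for constant. Conventions the rules leave open were fixed as:
"above the bottom quartile" is strict (>), "in the top quartile" is
inclusive (≥); quartiles use the linear-interpolation quantile and are
computed over peak-overlapping enhancers only, since non-overlapping
(no-response) signals are definitionally background. Rules are evaluated in
the order no_response → increasing → decreasing → constant; under the ε
floor the three signal rules are mutually exclusive (property-tested), so
order matters only for degenerate ties. Enhancers matching no rule go to an
explicit *unclassified* bucket — the four named labels do not cover the
signal space (a 1.2-fold change is none of them).

## Accessibility

Meta-profiles use 50 bp columns over ±3 kb (120 columns), in RPM/bp so
libraries of different depth are comparable; out-of-chromosome spans
contribute zero. The per-enhancer "increased accessibility" call is
fold ≥ 1.2 over the 1.5 kb summit window with the same ε floor. The 1.2
default is a judgement call — any threshold must exceed 1 and sit above
counting noise — and the fraction-increased headline moves with it, so it is
exposed prominently (`faire_increase_fold`).

## Gene dynamics

The genomic region for gene-level acetylation is the main free parameter of
this stage: default gene body + 2 kb upstream (strand-aware), with a
promoter-only TSS ± 1 kb alternative. Change is log2 of the input-normalized
ratio with pseudocount 0.5 on both sides. Group comparison uses the
pooled-variance Student *t* (not Welch): with triplicate groups this gives
df = 4 and the familiar 2.78 two-sided critical value at α = 0.05.
Zero-pooled-variance degenerate inputs return t = 0, p = 1 for equal means
and p = 0 (logged) otherwise. Expression input is a two-condition abundance
table classified by the symmetric, inclusive 1.5-fold rule; differential
calling from raw counts with dispersion modelling is out of scope.

## Motif enrichment

PWMs score as Σ log2(p/bg) with an additive pseudocount (default 0.01,
renormalized); N bases contribute 0 bits; both strands are scanned and
reverse-strand hits are reported at their forward-coordinate window start.
The default hit threshold is 80% of each matrix's maximal score. Enrichment
is presence/absence (≥ 1 hit per sequence) against all enhancer sequences as
the universe — robust to length variation, though not length-matched — via
the hypergeometric upper tail, BH-adjusted across motifs. The EcRE consensus
for real data is a required user input; `SYNTHETIC_ECRE_CONSENSUS`
(`RGGTCANTGACCY`, a canonical nuclear-receptor inverted repeat) is the
documented stand-in used by the synthetic tests, and the bundled PWM panel
(EcR-like, Eip74-like and three neutral fillers) is likewise synthetic, not
a database export.

## Bench-assay arithmetic

ΔΔCt averages triplicates before differencing and assumes amplification
efficiency 2.0 throughout; replicate scatter can be propagated to a
fold-change SEM by the delta method. Percent input takes the input dilution
fraction as an explicit parameter (no dilution-corrected input Ct is
assumed). FAIRE recovery accepts quantities or Ct values.

## The synthetic-data generator

The generator's purpose is statistical structure, not sequencing realism:
signals are deterministic Gaussian read bumps (σ = 150 bp) over Poisson
background, with no read-level artifacts, no replicate variability and no
FASTQ output. The genome is laid out in 10 kb slots — enhancer summit near
2 kb (snapped to the bin grid), gene TSS at 7 kb — so planted enhancers are
always TSS-distal while a configurable 5% of decoy peaks sit
promoter-proximal and must be rejected by discovery.

Category fractions (13.6% increasing, 8.2% decreasing, 15% constant, 10%
no-response, remainder unclassified) are apportioned as exact counts, not
multinomial draws, so recovered fractions measure pipeline fidelity rather
than sampling noise; the same holds for the 55% accessibility coupling and
the per-category motif-planting rates (60% for the receptor motif in
increasing enhancers, 5% baseline). Per-category stimulated/unstimulated
fold ranges (increasing 1.8–4.0, decreasing 0.30–0.55, constant 0.98–1.02,
unclassified 1.12–1.25) sit clear of the 1.5× / 33% / 10% rule thresholds
by design, and read depths (median bump amplitudes 800–4000 reads, input 8
reads/bin) keep window-level measurement noise around 3–5%, so rule
boundaries are rarely crossed by noise.

Two modelling choices deserve emphasis. First, each slot carries a
condition-invariant "static" acetylation bump whose lighter condition is
inflated so both H3K27ac libraries hold identical planted mass: in a real
genome responsive enhancers are a small share of total acetylation, but in
a toy genome they would otherwise dominate, skew the stimulated library
~20% deeper and bias every RPM-normalized fold downward. Second, each gene
carries a promoter acetylation bump whose fold mirrors its expression
response, which is what couples the gene-dynamics stage to the planted
up/down classes. qPCR tables are produced by the inverse ΔΔCt relation plus
Gaussian Ct noise (σ = 0.08 cycles), closing the loop with the assay module.

What passing tests therefore show: the pipeline implements its stated rules
exactly, and recovers planted structure when classes are separated and
depth is adequate. What they do not show: performance under realistic
ChIP-seq fragment-length effects, replicate dispersion, copy-number or
mappability artifacts, peak-calling errors, or mass imbalance between
conditions that RPM scaling cannot absorb.

A note on one degenerate configuration: with *all* enhancers planted as
increasing, the strict bottom-quartile gate necessarily withholds ~25% of
the population (with identical signals, all of it) — the quartile gates are
population-relative, so saturated single-class configurations cannot reach
100% recovery by construction. The saturated-recovery test asserts exactly
this behaviour.

## Problem sizes and determinism

The default study scale is 1,000 enhancers plus 50 decoys and 1,050 genes on
four 2.7 Mb chromosomes, which exercises every stage at comfortable
statistical resolution while a full generate-plus-pipeline cycle completes
in well under a minute; tests use 40–200-enhancer bundles for per-module
checks. All randomness flows through `numpy.random.default_rng(seed)`; a
fixed seed reproduces the file bundle byte-for-byte, and the pipeline report
records SHA-256 checksums of every output so re-runs are verifiable.

## Known limitations

Quartile gates make classification population-relative: adding or removing
enhancers can relabel others. The accessibility threshold and the gene
region rule are judgement calls that materially affect their headline
numbers. Background sequences for motif enrichment are not length- or
composition-matched. WIG and bigWig input, peak calling, read alignment and
de novo motif discovery are out of scope.
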