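# Methods

This note documents the models behind `mabckit`, the defaults and why
they were chosen, and what the synthetic data do and do not emulate.

## Genome map and meiosis

Each chromosome carries a monotone piecewise-linear map between physical
position (1-based inclusive bp) and genetic position (cM), anchored at
(1 bp, 0 cM) and (physical length, genetic length). The bundled map uses
the ten *B. rapa* chromosome lengths (A01–A10, 20.7–45.2 Mb, 71.6–115.2
cM, 945.32 cM in total) with a single linear piece per chromosome, i.e.
a uniform recombination rate; denser anchor sets from a real linkage map
can be supplied as a TSV and refine the interpolation without any code
change.

Meiosis draws the crossover count per chromosome from a Poisson
distribution with mean `gen_len/100` (one expected crossover per
Morgan), places breakpoints uniformly in cM, and alternates strands from
a random starting strand. This is the no-interference model implied by
the Haldane map function `r = (1 − e^(−2d/100))/2`, which is also the
map function exposed for distance→recombination queries (Kosambi is
available as an alternative). No obligate chiasma is enforced, so a
chromosome can segregate without crossover — acceptable at these map
lengths (≈1 crossover per chromosome per meiosis).

Individuals store phase as per-chromosome pairs of donor-segment
interval lists in cM space. Genotype truth at any locus is an interval
lookup, exact and independent of variant density; this is what makes
dense "resequencing-like" genotyping of thousands of loci cheap.

## Synthetic parents and variants

The recurrent parent carries no donor chromatin; the donor parent is
donor end-to-end; both are fully homozygous, as expected for inbred
lines. Variants (SNPs and INDELs) are placed uniformly per chromosome at
configurable per-Mb densities. Defaults are 50 SNPs/Mb and 25 INDELs/Mb
(≈22 000 variants genome-wide): large enough that dense genotyping
resolves segment boundaries to tens of kb and that the marker-design
chain retains well over the required number of candidates per
chromosome, while keeping a full pipeline run in the order of seconds.
Real resequencing of these lines yields ~100× more variants; the
analysis is density-independent, so this scaling changes resolution, not
structure. Five percent of variants are flagged heterozygous in the
donor to exercise the homozygosity filter. INDEL lengths are geometric
(mean ≈ 2.9 bp), giving a realistic preponderance of short events with
~40 % at the ≥3 bp marker-design threshold.

The target locus is the G→C substitution at CDS position 1277 of *MLPK*
(G194R); its homozygous recessive state (`mm`) is necessary for
self-compatibility. Its genomic placement at A03:14,000,000 is a
synthetic choice: inside the region that stays linked to the target
through backcrossing, and clear of the candidate modifier segment on the
same chromosome.

## HRM marker design

Candidate markers are homozygous INDELs of ≥ 3 bp. For each, primers are
placed by a deterministic grid search over product length and start
offset in the ±150 bp flanks, subject to: primer lengths 18–23 bp, both
allele products 130–260 bp, primers fully outside the variant interval
(so they bind both alleles identically). The first feasible placement
wins; this is constraint satisfaction, not thermodynamic primer
optimisation (no hairpin/dimer screening), which keeps the procedure
reproducible and testable.

Melting temperatures come from the unified nearest-neighbor duplex
parameter set, shipped as an editable TSV (16 stacks with
reverse-complement symmetry, terminal A·T/G·C initiation terms, a
symmetry correction for self-complementary sequences):

    Tm = ΔH_total / (ΔS_total + R ln(C_T / x)) − 273.15

with the salt adjustment `0.368 (N−1) ln[Na+]` on the entropy — an
identity at the 1 M Na⁺ default. The stated reaction temperature of such
assays (37 °C) parameterises free-energy reporting, not Tm, which is
defined by the ΔH/ΔS ratio, so it does not enter the formula. Total
strand concentration defaults to 0.25 µM (typical PCR) with x = 4 for
non-self-complementary duplexes; both are exposed. Enthalpy/entropy
sums use exact summation (`math.fsum`) so a duplex and its reverse
complement get bit-identical Tm. Candidates are retained when the two
allele products differ by ΔTm > 0.5 °C (strict), the practical
resolution of HRM instruments.

Panel selection aims at even coverage in genetic distance: each
chromosome's map length is split into k equal cM bins (k = the requested
marker count, default totalling 131 with fixed per-chromosome counts),
and the candidate nearest each bin midpoint wins, ties broken by larger
ΔTm then smaller bp. An empty bin steals the nearest unused candidate
with a warning. The density report gives physical length/count (Mb),
genetic length/count (cM) and the maximum adjacent-marker gap per
chromosome; the genome-wide row is the mean of the ten per-chromosome
values. The maximum gap is measured between adjacent markers only, not
to chromosome ends.

The target SNP is invisible to HRM (no length difference), so it gets a
KASP-style competitive allele-specific marker: two forward primers
ending (3′) on G and C respectively, one common reverse primer, product
50–120 bp; the fluorescence decode is FAM+VIC → Mm, FAM → MM, VIC → mm,
no signal → no call.

## Selection

Backcross selection is two-fold at each generation: carriers (Mm) are
kept on the target marker, then ranked by PRm. For the large BC2, a
two-step scheme first ranks on three screening markers (the first panel
marker of A01, A02 and A09 — the choice of chromosomes spreads the
screen across the genome; within a chromosome the first marker is an
arbitrary deterministic pick) and keeps the top 96, then re-ranks the
survivors on the full panel. Ranking ties break lexicographically on
plant id for determinism. Missing calls are excluded from both PR
numerator and denominator. Segregation ratios are tested with the 1-df
chi-square goodness of fit without continuity correction (counts in all
intended uses are large).

## Segment analysis

Dense per-locus states are collapsed into maximal runs of equal state;
runs with fewer than `min_support` informative loci (default 3) are
absorbed into the better-supported flank, iterated to a fixed point —
this tolerates isolated genotyping errors (at a 2 % error rate,
three consecutive errors are ~10⁻⁵ per window). Boundaries between
adjacent runs are placed at the bp midpoint between the last locus of
one run and the first of the next — unbiased when recombination is
locally uniform — and the outer segments extend to 1 and the chromosome
end, so segments always tile the chromosome exactly. An error adjacent
to a boundary can displace it by up to `min_support − 1` inter-locus
spacings. Segment lengths are inclusive (`end − start + 1`). TSV export
keeps 1-based inclusive coordinates; BED export converts to 0-based
half-open.

The drag report returns the segment containing the target locus and its
flanking recombination positions, and flags the inconsistency of an
`mm` plant whose containing segment is homozygous recurrent. Shared
candidate segments are the intersection of all self-compatible carriers'
donor-carrying (non-recurrent) intervals minus the union of the
non-carriers'; the implementation is exact interval arithmetic and is
tested against a per-position brute-force scan.

## Compatibility-index model

The observed phenotype is CI = seeds / pollinated flowers (20 flowers by
default), classified SI (< 1), MSC (1–4), SC (> 4); pollen-tube counts
use SI (< 10), MSC (10–25), SC (> 25). The latent CI of a simulated
plant is

    CI* = base(target genotype) + Σ_j effect_j · dosage_j / 2 + ε,
    ε ~ N(0, σ), CI* clipped at 0,  seeds = round(CI* × flowers)

with base CI 0.1 for MM/Mm and 1.0 for mm, four modifier loci at the
midpoints of the candidate segments on A03, A06, A07 and A09, each
adding +3 CI per homozygous donor dose, and σ = 0.4. These values are a
stand-in architecture, not an estimate: they encode the qualitative
facts that the recessive target genotype is necessary but not sufficient
(an `mm` plant with no donor modifier alleles averages CI ≈ 1, MSC at
best), that a plant carrying donor modifiers reaches clear
self-compatibility (CI ≈ 7 with two homozygous modifier doses), and that
baseline self-incompatible plants must classify SI with high probability
(σ = 0.4 puts P(CI < 1) ≈ 0.99 for an MM plant; a larger σ would
misclassify over a tenth of them). All parameters are configurable.

## Pipeline and reproducibility

The orchestrated experiment follows the study design: 12 BC1, 1120 BC2,
768 BC3 plants, the top three BC3 carriers selfed, ten `mm` plants
selected per family. The selfed family size (60) is a package choice —
large enough to recover ten `mm` plants (expected 15) with near
certainty. Marker genotyping is error-free by default; dense genotyping
uses 2 % missing and 0.5 % error to exercise the smoothing in segment
delineation. All randomness derives from one master seed through
per-stage child streams; reruns are byte-identical, and stage failures
abort with a stage-labelled error.

## What the generator does not emulate

Sequence reads, alignment and variant calling are not simulated; the
dense genotype matrix stands in for the variant-calling product
directly, with idealised uniform error. There is no segregation
distortion, no crossover interference, no structural variation, and the
uniform per-chromosome recombination rate ignores centromeric
suppression — real marker cM positions from a linkage map would shift
panel spacing. The modifier architecture of residual self-compatibility
variation is unknown in reality; simulation results involving CI
segregation demonstrate the analysis machinery, not the biology.
Passing tests therefore show that the arithmetic, the design rules and
the selection logic behave correctly under the stated model, not that
the model exhausts the features of real backcross data.
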