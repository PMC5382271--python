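# Methods

## Coordinate model

All genomic coordinates are 0-based half-open internally; GFF3 (1-based
closed) and BED/bedGraph (0-based half-open) are converted only at I/O.
TSS and PAS are *boundary* coordinates of the annotated transcription
unit: on the plus strand the body is `[tss, pas)`, on the minus strand
`[pas, tss)`. An oriented window `(s, e)` in transcription-direction
nucleotides around a boundary `a` maps to `[a+s, a+e)` on plus and
`[a−e, a−s)` on minus, which makes every statistic exactly symmetric
under a coordinate-and-strand mirror of the whole dataset (a property the
test suite asserts). Metagene windows are half-open, `[−L, R)`, with
relative position 0 the first base downstream of the anchor boundary.

The PAS is taken as the annotated 3′ end of the unit; PAS annotations are
inputs and are never recomputed. The downstream gap of a gene is the
distance from its PAS to the nearest point of any other annotated unit
lying further in its direction of transcription, on either strand —
read-through invades downstream units regardless of their strand, so a
strand-agnostic neighbour is the relevant one. Equidistant neighbours
take the minimum. The default cohort filter removes genes shorter than
500 nt or with a downstream gap under 250 nt.

## Read-through quantification

The post-PAS window defaults to `[PAS, PAS+50)` — the computation counts
reads *from the PAS downstream*, and a symmetric window remains available
through the offset parameters. The gene-body window is `[TSS, PAS)` with
no margin trimming by default (margins are configurable). Genes with a
body count under 10 reads are flagged `excluded` rather than dropped, so
cohorts stay aligned across strains; the threshold guards against
unstable ratios at very low expression. Log2 fold changes use no
pseudocount; a zero WT index with a non-zero mutant index is flagged as
an infinite fold change and excluded from summaries.

Cohort-level testing has two modes: with a WT replicate available, the
mutant-vs-WT log2FC distribution is compared to the WT-replicate-vs-WT
null by a two-sided Wilcoxon–Mann–Whitney test; without one, a one-sample
Wilcoxon signed-rank test of the log2FC values against zero is used. The
null calibration of the signed-rank mode is verified empirically over
1000 seeded WT-vs-WT simulations (40-gene cohorts keep the loop cheap;
calibration is a property of the test, not of the cohort size).

Per-gene calls use a Kruskal–Wallis test whose observations are the
per-position post-PAS coverage values of each strain, normalized by that
strain's gene-body mean. The choice of observation unit is ours —
position-level values are the finest unit available from coverage tracks;
calls additionally require the mutant median to exceed the WT median so
that "significant" always means *more* read-through. P-values are
reported raw; Benjamini–Hochberg is available but off by default.

The PAS usage index, `1 − mean(downstream 50 nt)/mean(upstream 50 nt)`
clipped at 1, is a cleavage-efficiency proxy: complete cleavage and decay
of downstream signal gives 1, unimpeded read-through gives 0.

## Housekeeping normalization

Termination mutants accumulate intergenic signal, which inflates library
size and makes depth normalization misleading. Tracks are instead scaled
so a designated highly expressed reference gene has a fixed body count in
every strain. Because the read-through index is a within-gene ratio this
scaling cannot change it; it matters only for cross-strain overlays of
absolute coverage.

## Metagene profiles

Rows are built per gene in transcription orientation; positions that fall
off a chromosome are masked, not zero-filled, so edge genes do not drag
averages down. Point features are binned at single-base resolution.
Aggregation is per-position mean or median over unmasked rows with the
contributing gene count reported. Gaussian smoothing uses a discrete
sampled kernel normalized to sum 1 (truncated at 4σ, reflect padding);
the default σ of 10 nt is our choice and is exposed in the interface.
Crosslink and motif profiles can be divided per gene by transcript
abundance before aggregation; rescaling to a reference profile matches
maxima so signals of different units can share an axis, and "align start"
divides each curve by its leftmost value (falling back to the mean of the
first k positions when that value is zero).

ChIP enrichment is the per-base IP/input ratio with the input floored at
1 read to avoid division by zero.

## Motif statistics

The motif (UGUA by default) is matched on the transcribed strand with
T≡U; overlapping matches are all reported and a match position is the
genomic coordinate of its 5′ base. The site-level statistic is the
fraction of crosslink sites with at least one motif start within ±25 nt
on the site's strand (counting motif *starts*, a documented choice).
Per-gene "high motif" flags compare a gene's motif count in the PAS ± 250
window against the cohort mean with strict inequality, so an all-equal
cohort flags nobody; the averaging cohort is the filtered gene set in
use.

## Binding calls and peak calling

Call windows default to `[TSS−10, TSS+250)` and PAS ± 250 nt, oriented by
the gene. One feature in the window suffices by default (the detection
threshold is configurable), and features may support multiple
neighbouring genes. Overlap reporting enumerates all 2^k Venn regions and
every ordered conditional percentage with its numerator and denominator,
so the counts are auditable exactly.

The bundled peak caller is deliberately transparent: contiguous runs of
IP/input ≥ 2 spanning ≥ 50 nt become peaks, the summit is the ratio
argmax (leftmost on ties). It is adequate for synthetic data and small
genomes; users with production ChIP data can import summits from any
external caller as BED.

## Binding model and Kd fitting

Probe concentrations in anisotropy assays (40–75 nM) are not negligible
against micromolar dissociation constants, so the fit uses the
ligand-depletion (quadratic) form of the single-site isotherm rather than
the hyperbola; the two coincide when L ≪ Kd, so the choice is safe and
strictly more general. Anisotropy is assumed to mix linearly in the bound
fraction, i.e. no fluorescence-intensity change on binding.

Least squares runs over (Kd, r_free, r_bound) with Kd constrained
positive, initialized from the data (min, max, concentration at
half-range). Two situations produce a censored result reported as a lower
bound instead of a point estimate: a fitted Kd beyond the largest
titrated concentration, and a curve whose dynamic range is below 5× the
residual noise (a genuine but weak curve has a range tens of times its
noise, so the factor separates "flat" from "weak" cleanly). The reported
bound is the largest power of ten not exceeding the top concentration —
titrating to 2 mM yields "> 1000 μM". Standard errors come from refitting
noise-perturbed replicates.

## Synthetic data: what it emulates, and what not

The generator lays out equal-length genes (default 200 × 1.5 kb, 800 nt
apart, alternating strands) and draws per-base Poisson counts around
closed-form means:

* RNA-Seq: depth e_g on the body (lognormal across genes with σ = 0.5,
  mean 20 reads/nt; the first gene is a 100 reads/nt housekeeping
  reference), then θ·e_g·exp(−d/λ) at d nt past the PAS. θ is the
  read-through fraction per strain (defaults 0.05 WT, 0.40 mutant); the
  exponential with λ = 200 nt is the simplest one-parameter monotone
  decay. A constant Poisson background of 0.1 reads/nt on both strands
  models antisense/intergenic signal — it is what makes housekeeping
  normalization worth having, and it attenuates recovered log2FC by
  ~0.14 at the default depths (visible in the worked example).
* ChIP: IP mean = input × (1 + 8·Gaussian(PAS+160 nt, σ 40 nt)) on both
  strands (the signal is DNA-based), input 10 reads/nt.
* PAR-CLIP: crosslink counts ∝ relative transcript abundance × Gaussian
  envelope (PAS+80 nt, σ 20 nt) × 50-fold boost within 2 nt of a UGUA.
* Genome: i.i.d. uniform ACGT, with UGUA written on the transcribed
  strand at each position in [PAS, PAS+100) with probability 0.02. A
  motif-free background mode (scrubbing UGUA on both strands) supports
  statistics whose expectation must equal the plant probability exactly;
  the dedicated crosslink-site generator uses it to plant a nearby motif
  per site with a specified probability.
* Titrations: the ligand-depletion model plus Gaussian noise.

Every generator is a pure function of (config, seed) with independent
named substreams, so strains and assays can be regenerated separately and
reproducibly.

Not emulated: read-level artefacts (no FASTQ, no alignment or sequencing
error), fragment-length effects, transcript isoforms or alternative PAS
usage, chromatin copy-number or mappability biases, and crosslinking
sequence bias beyond the motif boost. Passing tests therefore demonstrate
the correctness and statistical calibration of the analysis on data whose
generative assumptions hold; they do not certify performance on real
libraries, where these nuisances exist.

## Problem sizes and numerical choices

Test and verification runs use the default 200-gene cohort for parameter
recovery and localization, a 40-gene cohort × 1000 seeds for null
calibration, 1000 sites for motif-fraction recovery, and 200 Monte-Carlo
replicates per titration protocol; each suite completes in seconds on one
CPU. Optimizer tolerances are 1e-12 (xtol/ftol/gtol); the brute-force
cross-check for the Kd fit scans 4000 log-spaced candidates with an exact
linear solve for the anisotropy endpoints at each. Ties in peak summits
take the leftmost position; degenerate inputs (empty cohorts, zero
curves, empty call groups, zero-abundance genes) raise explicit errors or
are masked, as documented per function.

## Known limitations

* The no-decay limit (λ → ∞) makes post-PAS tails from upstream genes
  accumulate through densely packed synthetic layouts; generator
  consistency is therefore checked by inverting the closed form at finite
  λ rather than assuming isolated genes.
* The peak caller is threshold-based and has no local background model.
* The per-gene Kruskal–Wallis observation unit (positions) treats
  adjacent bases as independent, which real coverage autocorrelation
  violates; its calibration on real data should be checked against
  replicate-based nulls.
* Censoring thresholds are powers of ten; titrations topping out just
  under a power of ten report a conservative bound.
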