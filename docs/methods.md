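# Methods

## The measurement problem

Individual HERV elements are members of large families of duplicated,
fragmented, near-identical sequences. Quantifying one element's expression
from 50 bp reads therefore risks systematic cross-assignment. The pipeline
takes the conservative route: a read contributes to an element's count only
if it matches that element **exactly** (zero mismatches) and **no other**
element in the library. Reads matching several elements are discarded, not
redistributed; this trades sensitivity (duplicated copies become invisible)
for per-element specificity, which is the property the downstream model
needs.

## Exact-match index

Alignment under a zero-mismatch rule is substring matching, so the index is
a hash from every length-L window of every element to its occurrence list
(element, strand). Both strands are searchable by default (each window and
its reverse complement are stored), matching the double-strand search of a
conventional aligner; a `stranded` mode restricts orientation. Windows
containing N are not indexed and reads containing N are unassignable.
L is the read length (50 by default); L < 16 is rejected because such short
windows multi-map almost everywhere. Elements shorter than L cannot receive
reads and are recorded as unquantifiable with a warning.

Uniqueness is enforced at the **element** level: a read occurring at two
positions within one element is still unique to that element. An
`alignment_level` switch discards any read with more than one alignment
(position × strand), reproducing the stricter `-m 1`-style aligner filter,
for comparison. Both mates of a pair are counted independently after
decoupling (R1 block then R2 block per input), so an error-free simulated
sample yields exactly twice its true counts — a deliberate, testable
consequence of decoupling.

The per-sample library size used for cpm is the total of unique-assigned
reads — the only denominator computable inside an element-library-only
pipeline. A whole-genome mapped-read total, when available, can be supplied
as an external `library_sizes` vector.

## Normalization

cpm = count / library size × 1e6, computed before filtering; an element is
retained with ≥ `min_cpm` (default 1) in at least `ceil(min_fraction × n)`
samples (default half). TMM factors follow the published definition: the
reference sample is the one whose upper-quartile count fraction is closest
to the mean; per sample, over elements positive in both, M and A log-ratios
are doubly trimmed (30% by M, 5% by A, by rank) and the factor is 2 to the
precision-weighted mean of surviving M values (inverse binomial
delta-method variances), rescaled to geometric mean 1. Fewer than 10
surviving elements triggers a factor-1 fallback with a warning. The
implementation agrees with the reference R implementation to ~1e-6 on
random matrices (cross-checked in the suite), though bitwise equality is
not a goal.

## Negative-binomial model

Counts are modeled as NB with variance μ + φμ². The design holds an
intercept, donor indicators and a treatment indicator; per-donor offsets in
the generator are shared across conditions, which is exactly the pairing
the donor columns absorb. Offsets are ln(effective library size). The GLM
is fit by vectorized Fisher scoring with step-halving, linear predictors
capped at ±30, convergence at relative deviance change < 1e-8 or 100
iterations; all-zero rows are placed at the boundary (mean → 0, deviance 0)
and flagged.

Dispersion estimation uses the Cox–Reid adjusted profile likelihood
APL_g(φ) = ℓ_g(β̂; φ) − ½ log det(XᵀWX), evaluated on a 23-point log₂-spaced
grid (2⁻¹⁶…2⁶) with parabolic interpolation of maxima:

- **common**: argmax of the summed APL;
- **trend**: elements are binned by average log₂ cpm into
  `min(20, m // 50 + 2)` bins; per-bin mean APL curves are smoothed with a
  3-bin moving average and linearly interpolated at each element's
  abundance; the per-element argmax of this shared curve is the trended
  dispersion;
- **tagwise**: argmax of APL_g + (prior_df / residual_df) × shared curve,
  i.e. weighted-likelihood empirical Bayes with prior_df = 10 by default.
  Using the same shared curve for trend and shrinkage makes the
  prior_df → ∞ limit coincide exactly with the trend and prior_df = 0 with
  the genewise maxima; tagwise values are clipped to the interval between
  the genewise and trended argmaxes so the shrinkage interpretation holds
  even under interpolation wobble.

This follows the common/trended/tagwise empirical-Bayes structure of the
standard edgeR-style analysis; numerical equivalence with any particular
implementation of it is out of scope — the contract is the recovery and
error-control behavior verified in the suite (e.g. a true constant φ = 0.1
is recovered within [0.07, 0.13] from 2,000 elements).

The treatment term is tested by LR = deviance(reduced) − deviance(full)
against χ²(1) (one parameter dropped). Nonconverged fits yield NaN p-values,
excluded from the BH multiplicity count m and reported separately. BH is
the step-up envelope adj_(i) = min_{j≥i} m·p_(j)/j capped at 1. Classes:
up if FDR < α and log₂FC > τ, down if log₂FC < −τ (α = 0.05, τ = 3,
strict inequalities). Fold changes are reported as 2^lfc rounded half away
from zero to an integer; log₂FC to 3 decimals.

A paired Wilcoxon signed-rank helper is included for comparison only: with
four donors its smallest attainable two-sided p is 0.125, so it cannot
drive an FDR < 0.05 call set and the GLM path is canonical.

## ddPCR model

With molecules partitioned uniformly across droplets, per-droplet occupancy
is Poisson, so λ = −ln(1 − positives/droplets) and copies per reaction =
λ × droplets. Saturated wells (all positive) have no finite estimate and
are flagged. Replicate wells are pooled by summing droplets and positives
before inversion (the maximum-likelihood combination), not by averaging
estimates. Expression is copies per million RPL27 copies; the
regularization constant c = 0.01 is added to the per-million value before
log₂ — the least-distorting placement that still prevents log 0 for
zero-copy wells; it is configurable. Droplet volume defaults to 0.85 nl
(early-generation instrument convention) and only matters for per-µl
concentrations, not ratios. The treated-vs-untreated comparison is a
classical paired t-test on per-donor log₂ values; zero-variance nonzero
differences are reported at the machine floor with a warning. Dose–response
tables report log₂FC per dose against the per-donor untreated baseline plus
a monotonicity flag. Amplicon sizes are computed only when a template
containing both primer sites is supplied; otherwise not evaluable.

## Synthetic data: what it emulates and what it does not

The generator mirrors the study conditions: four donors each untreated and
treated (10 µM), 50 bp paired-end stranded reads, ~300 elements in 10
families, strong |log₂FC| = 4 effects in LTR12 (up) and LTR16C/LTR33
(down), constant NB dispersion 0.1 (biological CV ≈ 0.32), donor offsets
with SD 0.25 log₂ units, element lengths 400–2000 bp, 5% exact duplicates
and 5% truncated fragments. Baseline log₂ means are Normal(5, 2) by
default; recovery analyses use a higher location (8) so effects sit at high
abundance. The abundance–dispersion map is φ(μ) = asymptote + amplitude/μ
with amplitude 0 by default. A dose series can be specified; treated means
apply the full family lfc whenever dose > 0 (RNA-seq dose–response is not
modeled — the ddPCR arm handles dose curves with its own Hill-type copy
model, EC50 = 1 µM, in `analysis/05_ddpcr.py`).

Reads are error-free by default (an optional uniform substitution rate
exists to verify that mismatched reads go unassigned, since the pipeline
discards them rather than correcting them); R2 is the reverse complement of
a window offset 150 bp from R1, clipped to the element end — pair geometry
is immaterial after decoupling. Quality strings are constant 'I'.

Not emulated: realistic base-quality/error profiles, rRNA contamination,
genomic context (read-through from neighboring genes), GC or length biases,
and positional coverage bias. Passing tests therefore demonstrate the
correctness of the assignment/statistics machinery under the stated model,
not robustness to those real-data artifacts.

All randomness flows from a single integer seed through independent
`SeedSequence` streams (library, counts, per-sample reads), so every
artifact is byte-reproducible; per-sample read streams are keyed by a CRC of
the sample name to stay independent of sample order.

## Problem sizes

Defaults were chosen so each analysis step completes in seconds and the
repeated-simulation checks in minutes on a single core: 300-element
libraries (~470k read pairs across 8 samples) for the worked example, 500
elements × 200 replicate datasets for the null error-control study, 2,000
elements for dispersion recovery, and 15,000-droplet wells for the ddPCR
round trip. These sizes are deliberate scale-downs of a production HERV
catalogue (>90,000 elements, ~100M reads); the statistical contracts tested
(FDR control, effect recovery, oracle equivalence) are size-stable.

## Known limitations

- The uniqueness filter makes byte-identical duplicates invisible by
  construction; their expression is attributed to no element (never the
  wrong one).
- With 4 donors (residual df 3) genewise dispersions are noisy; inference
  quality leans on the empirical-Bayes shrinkage, as in the standard
  pipeline this mirrors.
- The χ²(1) reference for the LRT is asymptotic; at very low counts it is
  approximate (the null simulation in the suite bounds the practical
  consequence).
- The exact-match index stores plain string keys; memory grows with total
  library bases × 2 strands, fine at synthetic scale but a production-size
  catalogue would want 2-bit packing.
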