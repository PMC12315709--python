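# Methods

This note documents the generative models, the estimators, their
calibration, and the numerical choices, in the order data flows through the
package. Units are base pairs (bp) unless stated; "decade" means a factor
of ten in genomic separation.

## Coordinate and format conventions

All coordinates are 0-based half-open (BED convention) at every module
boundary; 1-based inputs must be converted explicitly (`mitoloop convert
--one-based`). Motif centers are the floor of the interval midpoint, so
even-width motifs resolve deterministically. Contact lists are a minimal
5-column pairs-like text (`chrom1 pos1 chrom2 pos2 [count]`) with
intra-chromosomal records normalized to `pos1 <= pos2`; binned matrices are
upper-triangle triplet text with a self-describing header.

## Mitotic loop-array contact model (`sim_hic.simulate_mitotic`)

The mitotic chromosome is modelled as a linear array of condensin loops
emanating from a central scaffold, with no sequence preference.

* **Anchors.** A renewal process lays loop anchors from 0 to the chromosome
  end with Gamma-distributed gaps: mean `mean_loop_bp` (the species loop
  size), shape `gap_shape` (default 8, i.e. gap CV ≈ 0.35 — fairly regular
  loops; an exponential array blurs every loop-scale feature, and
  `gap_shape=inf` gives a perfectly regular array for testing).
* **Intra-loop contacts** (probability `w_intra`, default 0.6): a loop is
  chosen size-biased by length, and the two points fall inside it with
  separation density `s^-alpha_intra` (default 1.5) truncated to the loop.
* **Inter-loop contacts**: a loop pair at scaffold separation Δk (in loops)
  is chosen with weight `Δk^-beta_inter` (default 1.4); each point's
  position within its loop is drawn Beta(`anchor_bias`, `anchor_bias`)
  (default 0.1), concentrating contacts near the anchors. This scaffold
  locality is what produces the contact enrichment at one-loop genomic
  separation, and hence the local maximum of the P(s) log-derivative that
  the loop-size estimator reads out; with uniform placement the derivative
  rises monotonically onto a plateau and carries no loop-scale landmark.
* **Ensemble.** A library pools `n_cells` (default 64) independent anchor
  realizations. Anchors sit at different positions in every cell, so the
  binned population map has uniform coverage — matrix balancing is then a
  near no-op, as in real data, instead of selectively flattening the
  anchor-proximal signal of a single fixed scaffold.
* **Helical modulation** (optional; on in the mouse preset): inter-loop
  weights are multiplied by `1 + helix_amp * comb(Δg)` where the comb is a
  set of Gaussian bumps (width `helix_sigma_bp`, default period/12) at
  integer multiples of the helical turn. The turn size is
  `helix_period_bp * helix_pitch_factor` (default factor 1.3): the nominal
  period is defined as the *observable* secondary-peak position, and since
  a derivative peak sits at the left inflection of a bump — below its crest
  — the underlying turn must be somewhat larger than the peak it produces.
  A plain-cosine modulation (`helix_shape="cosine"`) is also available; its
  broad first harmonic places the secondary peak near 0.75 of the period,
  which is why the localized comb is the default.

The model is a statistical contact kernel, not a polymer simulation: it is
fast, seeded, and analytically inspectable, at the cost of not producing
3-D coordinates or mechanistic exponents.

## Interphase contact model (`sim_hic.simulate_interphase`)

Separations are drawn from a two-component mixture: a power-law background
`s^-bg_exponent` (default 1.1) and a lognormal bump of cohesin
anchor-anchor contacts centred at `cohesin_loop_bp` (default 100 kb; width
0.15 decades; fraction `loop_fraction` = 0.15 of contacts). The bump is
the interphase analogue of the mitotic scaffold-locality term and gives the
derivative curve its ~100 kb local maximum.

Motif-dependent structure multiplies the sampled proposal weight:

* **Insulation**: each motif strictly between the two contact ends
  attenuates the weight by its category's factor
  (defaults bookmarked 0.35 < reduced 0.55 < lost 0.75 — insulation
  strongest at bookmarked sites).
* **Loop dots**: convergent motif pairs (+ upstream, − downstream, ≤250 kb
  apart) add a 2-D Gaussian enrichment (σ = 10 kb) scaled by the category
  dot strength (4.0 / 2.0 / 0.8).
* **Stripes**: each motif adds a one-directional enrichment along its
  extrusion direction (Gaussian across the anchor, exponential reach
  150 kb; strengths 1.5 / 0.8 / 0.3).

Sampling is by importance resampling from a 2× oversampled proposal pool,
which draws exactly from the product density (duplicate records can occur,
as in real pair lists). Category strength orderings are model inputs that
encode the qualitative contrast under test, not measured values.

A consequence of both loop terms: P(s) is not strictly nonincreasing — the
loop-scale enrichment lifts it locally by some tens of percent. Decay is
monotone outside a window of roughly [L/3, 3L] around the loop scale, and
the property tests check exactly that.

## ATAC footprint model (`sim_atac`)

A bound CTCF protects `[-40, +40]` around the motif center and phases the
neighbouring nucleosomes, leaving accessible cut sites at the ladder
offsets ±40, ±240, ±420, ±600 (chosen so core-spanning fragments measure
exactly 80/280/460/640 bp — reverse-engineered from the dot positions, not
a measured nucleosome repeat). Beyond the ladder, cutting is uniform at
`distal_rate` (1/50 bp) out to ±1000. A fragment is a pair of consecutive
cuts of this inhomogeneous process: pair weight = end intensities ×
`exp(-accessible intensity between)` × `span_decay^(units-1)` for the
protected units (core, nucleosomes) fully spanned. Cut positions get
Gaussian jitter (σ = 2 bp); minus-strand sites mirror the geometry. Unbound
sites cut uniformly across the whole window with exponential fragment
lengths (mean 50 bp), which produces the sub-50 bp enrichment at open
motifs without a separate short-fragment term. Tn5's 9-bp duplication is
ignored — a cut is a single breakpoint, since V-plot geometry rather than
enzymology is under test.

Per-category binding probabilities by phase default to
bookmarked (1.0, 1.0), reduced (1.0, 0.5), lost (0.8, 0.0)
(interphase, mitotic); the library records every site's drawn state in a
manifest for ground-truth evaluation.

## Matrix operations (`matrix`)

Counts are binned into sparse upper-triangle matrices. Balancing follows
iterative correction: marginals are computed excluding the first
`ignore_diags` (default 2) diagonals; bins whose log coverage is more than
`mad_max` (default 5) median absolute deviations below the median, or with
zero coverage, are masked; weights are updated by the square root of the
normalized marginal until the variance of normalized marginals falls below
`tol` (default 1e-5, max 200 iterations — non-convergence is a warning,
not an error, since sparse real maps may not converge). Weights are scaled
so the mean unmasked marginal is 1, which makes balanced values scale as
1/counts under count rescaling. Expected-by-distance is the per-diagonal
mean over unmasked pairs (zeros count); O/E divides balanced values by it,
flagging masked bins and ignored diagonals as missing. Pile-ups average
O/E snippets entrywise over available values (never zero-filling, which
would bias sparse bins downward); minus-strand snippets are flipped at the
array level, so strand negation reverses the pile-up axes exactly.

## P(s), derivative, and loop-size estimation (`scaling`)

P(s) is contacts per locus pair in logarithmic separation bins (display
default 8 bins/decade; the estimation pipeline uses 16 so that peak
refinement is not resolution-limited). From a balanced matrix the
per-diagonal sums and unmasked pair counts are aggregated; from raw
contacts the locus-pair denominator is the exact integer sum of `G - s`.
The log-log derivative applies Gaussian smoothing (σ = 0.1 decades) to
log₁₀P over log₁₀s — with linear extension at both ends so an exact power
law returns its exponent everywhere — followed by centred differences.
Peaks are strict local maxima; each position is refined by a least-squares
quadratic vertex over the ±2-bin neighbourhood, clamped to half a bin
(unclamped 3-point refinement drifts on asymmetric peaks).

The estimator reports `L̂ = s_peak / c_cal` with the first peak in the
regime's search window (interphase 30 kb–1 Mb; mitotic 100 kb–5 Mb). The
calibration constant is the median ratio `s_peak / L` over a generator grid
(five loop sizes × three seeds per regime, `scripts/calibrate.py`), frozen
in the preset registry: mitotic 0.5886, interphase 0.6011. The measured
ratio is constant to ±3% across loop sizes 250 kb–1.25 Mb and seeds, so the
calibrated estimator recovers the generator's loop size to a few percent at
3×10⁶ contacts. Peaks below ~0.6× the window minimum (loop sizes under
about 170 kb in the mitotic window) are undetectable by construction; the
estimate is then reported undefined rather than guessed.

## V-plot metrics (`vplot`)

V-plots use ±1000 bp offsets, lengths up to 800 bp, 4-bp bins (the axis
choices are package conventions). The arm crossing scans the central
columns for the smallest-length local maximum above 56 bp and requires
supporting ridge mass on both arms above local background; positions are
centroid-refined, so the crossing reports ~80 despite 4-bp bins. Arm dots
are local maxima of the ridge profile (`ℓ = 2|x| + cross`, both arms
summed) with prominence above 3× the median ridge-adjacent background.
The footprint score is the log2 ratio of per-area densities in the core
band (|x| ≤ 20, ℓ 60–100) versus the short band (ℓ 20–50) with add-one
smoothing; a positive score classifies bound. Per-site classification is
count-limited: the bands hold only a handful of fragments per few hundred,
so the ground-truth accuracy check runs at 2000 fragments per site, where
accuracy saturates near 100%.

## Compaction statistics (`compaction`)

The q-arm is `max(centromere, length - centromere)`; p + q equals the
chromosome length exactly. Compaction is `qarm_mb / chromatid_length_um`
per chromatid. Group comparison defaults to the pooled-variance Student
t-test (two-sided), with Welch available by flag; degenerate equal-constant
groups return t = 0, p = 1. The loop-size versus longest-q-arm relation
uses Spearman rank correlation and requires at least three species; fully
tied tables are flagged undefined. The measurement simulator draws
per-chromatid ratios Normal(true ratio, SD) and converts to physical
lengths at fixed genomic arm size; real karyotype or measurement tables are
user-supplied CSVs, never bundled.

## What the synthetic data do and do not show

The generators encode the *structures* the analyses are designed to detect
(loop arrays with a defined mean size, helical periodicity, category-graded
CTCF features, footprint ladders) under seeded, homogeneous sampling. They
omit: compartments, trans contacts, sister chromatids, coverage and
mappability bias beyond what balancing removes, sequence-dependent Tn5
bias, read-level artefacts, and polymer physics. Passing tests therefore
demonstrate that the estimators are correct and calibrated for data whose
generating process matches the model family — not that they are robust to
every artefact of real libraries. The calibration constant in particular is
generator-specific: applied to real Hi-C it would recover the derivative
peak position up to a model-dependent factor of order one.

## Problem sizes

Default test and acceptance runs use one 150 Mb chromosome at 3×10⁶
contacts for scaling analyses (25–50 kb bins mitotic, 10 kb interphase), a
100 Mb chromosome at 4×10⁶ contacts for pile-up contrasts, and 200-site
fragment libraries for footprinting — sizes at which every quantity under
test is stable across seeds while the full suite runs in a couple of
minutes.
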