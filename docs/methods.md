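# Methods

## Gradient simulation

Each taxon's DNA is modelled as a Gaussian mass density over buoyant density
(BD), centred at

    μ(taxon) = bd_unlabelled_mean + atom_fraction_13C · bd_full_label_shift

with `bd_unlabelled_mean = 1.7066 g/ml` and `bd_full_label_shift =
0.0311 g/ml` — the midpoint of the packaged light window (1.7042–1.7089) and
the separation of the two window midpoints, respectively — and a
within-taxon spread of `bd_within_taxon_sd = 0.006 g/ml`, chosen so the two
windows separate cleanly for fully labelled DNA.  The density is evaluated on
the 14-fraction BD grid (default 1.755 → 1.690 g/ml, fraction 1 densest, BD
exactly linear in fraction number), perturbed by per-(taxon, fraction)
lognormal noise (`abundance_noise_cv = 0.10`, a typical compositional
fraction-to-fraction variability for amplicon data), and renormalised so each
taxon's summed mass equals its base abundance exactly — conservation holds to
1e-9 by construction, not approximately.  Column normalisation then yields
per-fraction relative-abundance tables (compositional, summing to 1) and
per-fraction 16S copy totals proportional to total DNA mass.

Both treatments consume an identically seeded random stream, so a
zero-labelling configuration produces bit-identical ¹²C and ¹³C runs, and the
mean BD of a taxon is provably monotone in its atom fraction (the noise acts
as a fixed positive reweighting of a location family).

The default synthetic community is a geometric rank-abundance curve (ratio 0.96,
100 taxa) with two fully labelled taxa 17 ranks apart, giving them a ~2:1
abundance ratio; both sit comfortably inside the top-100 abundance ranks.

What this generator does *not* emulate: taxon-specific GC-driven differences
in unlabelled BD, partial labelling heterogeneity within a taxon, PCR/chimera
artefacts, and replicate-level variance.  Passing recovery tests therefore
show that the statistics behave correctly under their own assumptions, not
that real gradients are this clean.

## Window detection

BD is regressed on fraction number by ordinary least squares (constant-BD
runs are flagged degenerate rather than fitted).  Window detection normalises
each run's 16S copies to its total (treatments can differ in recovery), then:

* **heavy** — among fractions with BD above `bd_split = 1.72 g/ml`, the
  largest contiguous block in which the ¹³C copies exceed the ¹²C copies by a
  factor ≥ `ratio_min = 1.5` *and* carry at least `min_copy_frac = 0.001` of
  the ¹³C run's copies.  The copy floor exists only to reject
  near-zero/near-zero ratios at the very dense tail of the gradient, where
  both profiles vanish; it is deliberately far below any fraction with real
  signal so that the ratio criterion decides membership everywhere else.
* **light** — the contiguous block below the split around the ¹²C copy peak,
  grown while copies stay ≥ 50% of the peak.

The window is the closed BD span of the block; a single-fraction block is
padded by half the inter-fraction spacing (a fraction represents a BD bin,
not a point).  When no heavy block qualifies (no labelling signal), the
packaged default windows are returned with `fallback=true` so downstream
stages still run and the condition is visible in every report.

## REF calling

Window aggregates are unweighted means of an ASV's relative abundance over
the fractions classified into each (treatment, window) — the mean is
scale-stable across window sizes, and nothing in the ratio-of-ratios
definition favours any other weighting.  The pseudocount (1e-6) is added to
all four terms *only when at least one is zero*, so exact inputs give exact
ratios.  Ranking for the top-N rule uses the mean relative abundance over all
windowed fractions of both treatments, descending, ties broken
lexicographically; the threshold comparison is strict (REF > 2.0).
Replicate averaging before aggregation and qPCR-copy weighting of abundances
are deliberately not defaults; both can be realised by preprocessing the
input table.

## Raman simulation and classification

Simulated spectra live on a 600–1800 cm⁻¹ grid (1 cm⁻¹ step): pseudo-Voigt
bands (50/50 Gaussian/Lorentzian, FWHM 8 cm⁻¹ — a typical Raman linewidth),
with the phenylalanine band at 1001 cm⁻¹ (unlabelled) or 968 cm⁻¹ (labelled),
four accessory cell bands placed outside the 1500–1700 cm⁻¹ noise-estimation
region, a quadratic baseline, per-cell lognormal gain variation (CV 0.2) and
additive Gaussian noise (σ = 0.02 for unit band amplitude, i.e. peak SNR
≈ 50, representative of well-focused single-cell acquisitions).  Ground-truth
labels are stored in spectrum metadata and never read by the classifiers.

Preprocessing is order-fixed: baseline correction, then vector normalization
(unit Euclidean norm), making all downstream quantities invariant to
instrument gain.  The baseline estimator is asymmetric least squares
(Whittaker smoother, λ = 1e5, p = 0.01, ≤10 reweighting iterations with early
stop), solved via banded Cholesky in O(n).  Two refinements:

* the trace is extended by odd reflection (50 points) before smoothing, which
  removes the boundary lag the smoother otherwise shows where baseline
  curvature is high;
* after the ALS iterations, if the residual contains narrow high-prominence
  peaks (actual bands), those points are masked and the baseline re-smoothed
  once with symmetric weights.  Without this step, every pass of plain ALS
  subtracts a further O(p·height) dip under each band, so correction is not a
  stable operation; with it, correcting a corrected band-bearing trace
  changes it by ≪1% RMS.  Band-free traces show only broad residual
  structure, the trigger does not fire, and the plain ALS estimate (which
  tracks such baselines well) is kept.  On noisy traces a repeat correction
  can still drift by the order of the noise sigma — inherent to any
  quantile-seeking baseline estimator.

Band detection searches for the highest-prominence local maximum in the
labelled window (955–980 cm⁻¹, bracketing both a 968 cm⁻¹ band and the
−37 cm⁻¹ shift variant) and the unlabelled window (990–1010 cm⁻¹), keeping a
peak only if its prominence exceeds 3× the noise sigma, estimated as the MAD
of successive differences in 1500–1700 cm⁻¹ (robust to smooth residual
structure; exactly zero for noiseless traces, where any true peak is then
kept).  A cell is called labelled when a labelled-window peak exists and is
taller than any unlabelled-window peak; the shift is reported relative to the
1001 cm⁻¹ unlabelled biomarker position.  The two shift conventions in circulation
(1001→968, i.e. −33 cm⁻¹, and a −37 cm⁻¹ redshift) are inconsistent with one
another; the simulator defaults to 1001→968 and both positions are plain
parameters, so neither convention is hard-coded.

Group band-intensity comparisons use one-way ANOVA on the intensities at the
968 and 1001 cm⁻¹ grid points of the preprocessed spectra.

## Cultivation design

Medium rules are keyword matches over free-text/KO-style annotation labels
(case-insensitive substrings; the trace-metal rule additionally requires a
transport-context word so that e.g. "zinc finger" does not fire).  Each rule
fires at most once and records its triggering labels:
vitamin-metabolism genes → vitamin stock 10 ml/L; trace-metal transport →
mineral stock 10 ml/L; aminoglycoside resistance → streptomycin 5 mg/L;
lactate dehydrogenase → L-lactate 50 mM.  The rule table is an ordinary data
structure and can be edited or replaced per study.

Consortium ratios snap log2(abundance_a/abundance_b) to the nearest of
{1, 0, −1} → {2:1, 1:1, 1:2} — the only mixtures of interest — with a 1e-9
tolerance at the midpoints so the exact boundary (a/b = √2, not
float-representable) resolves toward 1:1 as intended.

Degradation efficiency is raw removal, `100·(c₀−c_t)/c₀`, clipped below at 0
and not corrected for abiotic losses by default (matching the common
reporting convention); a sterile-control-corrected variant is provided for
studies that subtract abiotic losses.

## Problem sizes and determinism

All simulations are seeded through a single integer per configuration; every
test and script is deterministic given its seed.  The shipped analyses use
100 taxa × 14 fractions × 2 treatments and 800-cell Raman screens; recovery
properties are checked over 50 gradient seeds and 20 spectra seeds, sizes at
which the full suite completes in about a minute while still exercising the
multi-seed stability claims.

## Known limitations

* REF is a point statistic; no replicate-level uncertainty or bootstrap is
  attached (deliberately out of scope).
* Window detection assumes a single contiguous heavy block; bimodal labelling
  (two separated heavy peaks) would be truncated to the larger block.
* The Raman classifier is a two-window peak comparison, not a spectral
  unmixing; partially labelled cells with split band intensity are called by
  whichever window peak is taller.
* Isopycnic physics beyond the linear BD–fraction relationship (e.g. the
  GC-dependence of unlabelled BD) is not modelled.
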