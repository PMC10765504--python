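# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Experimental design being modelled

Three treatments mix a 30% whole-seawater inoculum with 70% of 0.2 µm
filtrate: S/S (surface/surface control), S/D (surface cells on formerly
suboxic deep DOM) and D/S (deep cells on surface DOM), two replicate
bottles each, sampled densely over days 0–6 and then on days 8, 9, 12
and 21. Expected starting concentrations follow conservative mixing,
`expected = f·filtrate + (1−f)·inoculum` with f = 0.70; measured starting
values are compared against these to verify the dilution.

## QC: the DOC contamination rule

Within each (treatment, bottle) DOC series, values strictly greater than
the group's 90th percentile (sample quantile with linear interpolation
between closest ranks) are flagged `contaminated`. Flagged rows are
retained in all output tables but excluded from fits and integrals.
Groups with fewer than 5 observations are skipped with a warning. The
grouping is configurable because a per-series percentile rule necessarily
flags the initial maximum of a cleanly decaying series; when that removes
the T0 observation, the BGE integration window is truncated to start at
the first QC-valid timepoint and the result carries the flag
`window truncated at first valid observation`.

## Growth kinetics

Abundance trajectories are fitted with the logistic
N(t) = K / (1 + ((K−N0)/N0)·e^(−rt)) by bounded least squares on
**log-abundance residuals**. The log scale is the maximum-likelihood
choice for multiplicative (lognormal) count error — the error structure
cell counts actually show, and the one the synthetic generator uses — and
it conditions slow-growth fits far better: with linear residuals and a
5% coefficient of variation, the capacity of an S/S-like series is close
to unidentified and the stationary estimate ranges over two orders of
magnitude across noise realisations.

Deterministic initialisation: K₀ = max observation, N0₀ = first
observation, r₀ = log-slope of the first three points (0.1 if
non-positive); bounds K ∈ (max obs, 10·max obs], N0 ∈ (0, max obs],
r ∈ (0, 20] d⁻¹. Identical inputs give identical fits. A series that
never exceeds its initial value raises "no growth signal".

Derived quantities: t_mid = ln((K−N0)/N0)/r, stationary onset
t_stationary = 2·t_mid, and the exponential window
[t_start, t_stationary], where t_start is the time of the minimum
observed abundance before t_mid — this accommodates the deep-inoculum
treatment's initial die-off, whose declining segment a logistic cannot
represent. When such a die-off is detected (the pre-t_mid minimum falls
after the first timepoint), the logistic is refitted on the post-minimum
segment (two-pass fit) so the die-off points do not bias K and t_mid.
μ is the OLS slope of ln(abundance) over the window, requiring ≥3
observations; fewer raise an error asking for a manual window override
(reported per bottle as a diagnostic row, not a pipeline abort). On noisy
slow-growth series this error is the honest outcome of an unconstrained
stationary estimate.

Bacterial carbon uses 20 fg C cell⁻¹ (configurable) and a carbon molar
mass of 12.011 g mol⁻¹:
µmol C L⁻¹ = cells L⁻¹ × fg_cell × 10⁻¹⁵ / 12.011 × 10⁶.
BGE = ∫BC/∫DOC over [T0, t_stationary], integrating the excess of biomass
carbon above its T0 value and the deficit of DOC below its T0 value by
the trapezoid rule, with window endpoints linearly interpolated between
samples. The shared time-normalisation cancels in the ratio, and the
ratio is invariant to adding a constant to the DOC series. ∫DOC ≤ 0 is
reported as "no net DOC removal" with an undefined (NaN) BGE rather than
a signed ratio.

## Amino-acid diagenesis

Molar fractions are per-sample mol% (summing to 100); TDAA carbon is
Σᵢ concᵢ·Cᵢ with carbon counts from the amino acids' chemical formulas;
TDAA yield is (TDAA-C/1000)/DOC × 100 (%). The degradation index is

    DI = Σᵢ [(varᵢ − AVGᵢ)/SDᵢ] · fac.coefᵢ

over a reference table of per-acid mol% means, SDs and first
principal-component factor coefficients. The packaged table
(`data/aa_reference_synthetic.csv`) is a **synthetic stand-in**: its
values carry the conventional structure (glycine/serine/threonine
enriched in degraded material → negative coefficients; glutamic acid and
hydrophobic acids enriched in fresh material → positive), its means sum
to exactly 100, and its carbon counts are exact; but the numbers are not
a transcription of any published reference set. Every DI result in the
test suite therefore relies only on structural properties (DI = 0 at the
reference composition, linearity in single-acid z-perturbations, scale
invariance), and users analysing real data should load a transcribed
published table via `AAReference.from_csv`. Amino acids present in a
profile but absent from the reference's DI set contribute to TDAA and
mol% but not to DI.

## FT-MS molecular indices

DBE = ½(2 + 2C − H + N + P); half-integral values (nitrogen-rule parity
violations) are flagged, not rejected. The default aromaticity index is
the modified form AI_mod = (1 + C − ½O − S − ½(N+P+H)) / (C − ½O − N − S − P),
clamped to 0 for negative numerators or non-positive denominators; the
unmodified variant (full oxygen weighting) is available by flag.
Compound classes come from an ordered rule table over H/C, O/C, AI,
DBE/C, DBE/H, DBE/O and heteroatom presence; the first matching rule
wins and unmatched formulas are "unassigned". The shipped boundaries are
literature-conventional heuristics (condensed aromatics at AI ≳ 0.66
with black carbon additionally requiring C ≥ 15; polyphenols at
0.5 < AI ≤ 0.66; carbohydrate/sugar, peptide/protein, lipid and
saturated-fatty-acid boxes in the van-Krevelen plane; CRAM by the
DBE/C ∈ [0.30, 0.68], DBE/H ∈ [0.20, 0.95], DBE/O ∈ [0.77, 1.75]
windows) and are deliberately exposed as data so a different boundary
set can be substituted; class compositions should be read as
rule-relative, not absolute. Magnitude-weighted indices are
Σ(magᵢ·xᵢ)/Σmagᵢ over all formula-assigned features by default
(classified-only by flag); features without formulas count toward
`n_features` only. CHO/CHON/CHOS counts partition assigned formulas by
heteroatom content; formulas with both N and S are reported separately
(`n_CHONS`).

## qPCR

Standard copy numbers follow copies = ng·6.0221×10²³/(bp·10⁹·660).
Standard curves are OLS of Cq on log₁₀(copies) over ≥3 distinct levels
(10⁶–10¹ by default); efficiency = 10^(−1/slope) − 1 (100% at the
perfect-doubling slope −3.3219; a slope of −2.93 gives 119%). Positive
slopes flag the curve invalid. Unknowns are quantified by inverting the
curve; Cq values outside the standards' span are returned with an
out-of-range flag. Replicate wells are merged by mean Cq per
(sample, gene) before quantification (configurable); amplification in a
negative control logs a plate-level warning. Copy numbers are normalised
per ng of template DNA.

## Community summaries

ASVs with non-zero counts in fewer than 4 samples are removed, then
samples are rarefied to exactly 10,000 reads by a seeded multivariate-
hypergeometric draw (exact subsampling without replacement); samples
below depth are dropped with a notice. Filter-then-rarefy is the default
order (both orders available). Shannon uses natural log; "Simpson" is
the Gini–Simpson index 1 − Σp². Family-level relative abundances pool
groups below 1% of the experiment-wide total into "other"; the separate
>0.15% ASV threshold for plotting tables is an independent configurable.
Copy-number adjustment divides a taxon's percentage by its 16S operon
copy number and by default reports it against the *original* total (so
75% at 3 copies → 25% of total ASVs); the renormalised variant (rescale
to 100%) is statistically preferable when comparing adjusted
compositions and is available by flag.

## Statistics

Treatment effects: one-way ANOVA with Tukey HSD pairwise comparisons,
per timepoint or pooled. When every observation is identical the
degenerate ANOVA is reported as F = 0, p = 1. Replicate equivalence is a
two-sided paired t-test on per-timepoint bottle differences pooled
across treatments (an exact sign-flip permutation variant is available);
inside the pipeline, timepoints unpaired because of QC flagging are
intersected away rather than raised. No multiple-testing correction is
applied across analytes (Benjamini–Hochberg available, off by default).

## Synthetic generator

The generator produces the statistical structure the pipeline assumes —
not a mechanistic biogeochemical model. One integer seed drives a single
`numpy.random.Generator`; identical (config, seed) pairs give
byte-identical bundles, and the manifest (config + seed + version)
regenerates a bundle exactly.

Defaults are the study conditions: growth rates 0.03/0.19/0.11 d⁻¹ and
exponential durations 10.1/4.9/2.8 d for S/S/S-D/D-S; initial abundances
30% of 17.6×10⁸ (surface) and 70.0×10⁸ (deep) cells L⁻¹; DOC starting
points from conservative mixing of 94.8 and 110.1 µmol C L⁻¹; a 25%
one-day die-off in D/S followed by regrowth; DOC first-order decay
toward a refractory floor with initial rates 0.79/2.7/0.68
µmol C L⁻¹ d⁻¹ and a 2 µmol C L⁻¹ production pulse peaking at day 12 in
D/S; qPCR standards on a −2.93 Cq/log₁₀ line (119% efficiency) with
0.15-Cq replicate noise; a deep-inoculum community 75% dominated by a
3-copy anaerobic family that collapses after reoxygenation; ASV library
sizes 12,000–25,000 reads. Noise is multiplicative lognormal for
abundances (mean-corrected, default CV 3%) and additive Gaussian
truncated at zero for concentrations (default 1 µmol C L⁻¹ for DOC) —
truncated sampling, not post-hoc clipping, so positivity never distorts
the mean structure.

Growth trajectories are calibrated at generation time: with window start
t_s (the die-off duration) and configured duration T, the capacity ratio
is ρ = exp(r·(T − t_s)/2) so that 2·t_mid − t_s = T exactly, and r is
found by Brent root-finding so the OLS ln-slope over the sampled days
inside [t_s, t_s + T] equals the configured μ exactly before noise. The
noiseless bundle is therefore a fixed point of the downstream analysis —
which is what makes parameter-recovery testing meaningful. BGE is *not*
calibrated: the configured kinetics fix μ and durations only, so the
synthetic bundles' BGE values are emergent, not targets.

What the generator does not emulate: oxygen and nutrient dynamics,
grazing and viral mortality, diauxic substrate shifts, chromatographic
or mass-spectral artefacts (the formula pool is a fixed set of
representative compositions), chimeras or sequencing error in ASVs, and
between-bottle systematic offsets. Passing tests on synthetic bundles
demonstrate that the pipeline recovers known structure under the stated
noise model — not that the biological conclusions from any real dataset
are correct.

## Numerical conventions and problem sizes

Percentiles use linear interpolation between closest ranks
(`numpy.percentile` default). Trapezoidal integration is used
throughout; on densely sampled smooth curves it agrees with adaptive
quadrature within 1%. Root-finding tolerances are 1e-13 (calibration)
and 1e-14 (fits). Rarefaction and all simulation draw from seeded
generators only — no time- or locale-dependent state. Test and
acceptance runs use the experiment's own scale (11 timepoints, 2 bottles
× 3 treatments, 300 features per sample, 30 ASV samples × 30 ASVs,
50-seed recovery grids), which keeps the full suite under a minute on
one CPU.

## Known limitations

- Printed BGE values for this experimental design cannot be
  reconstructed from summary tables alone (change-in-cells and
  DOC-removal entries are mutually inconsistent under any simple
  ΔBC/ΔDOC reading); the BGE definition here is the documented integral
  form, validated on closed-form synthetic trajectories instead.
- The spec-style invariant "μ → r as N0/K → 0" does not hold for an OLS
  ln-slope taken over the full window [t_start, 2·t_mid]: with uniform
  sampling the limit is ≈ r/2, because ln N is nearly piecewise linear
  (slope r, then 0) around t_mid. The true invariants — μ ≤ r, μ
  between ≈ r/2 and r — are what the tests assert.
- Slow-growth series near the noise floor can yield unconstrained
  stationary estimates; these surface as explicit per-bottle diagnostics
  and are the expected behaviour of the estimator, not a pipeline fault.
- The amino-acid reference table is a labelled synthetic stand-in (see
  above); DI values from it are structurally correct but not comparable
  to published DI scales until a transcribed reference is supplied.
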