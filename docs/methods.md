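# Methods

## Optical model

The sensor is modelled as a stack of homogeneous, isotropic layers:
semi-infinite incident prism, gold film, zero or more adsorbed slabs,
semi-infinite buffer. p-polarised intensity reflectance is computed with
the Abelès characteristic-matrix method, vectorised over the angular
scan; an independent recursive Parratt implementation of the same
physics is kept in the public API purely as a cross-check (the two agree
to ~1e-15 on random passive stacks, asserted at 1e-10 in the tests).
Angles are internal incidence angles inside the prism, in degrees;
responses are reported in millidegrees as instrument software does.
Only p polarisation is implemented, since surface plasmons do not couple
to s-polarised light. The normal wavevector component in each medium
takes the decaying branch Im(k_z) ≥ 0; for passive media (k ≥ 0,
enforced) reflectance is clipped to [0, 1] only to absorb sub-epsilon
rounding excursions.

Gold optical constants ship as a small built-in n+ik table at
600–800 nm (Johnson & Christy-style literature values) with linear
interpolation; any layer can override its dispersion with an explicit
map or callable, and a TOML config can patch individual table entries.
A chromium adhesion layer is not included by default but is expressible
as an ordinary layer. The default sensor configuration is
prism n = 1.515 | Au 50 nm | water n = 1.333.

**Dip localisation.** The SPR dip is the intensity-weighted centroid of
the spectrum below a threshold T = R_min + f·(R_edge − R_min), where
R_edge is the lower of the two window-edge reflectances and f defaults
to 0.5 (the threshold fraction is not standardised across instruments
and is exposed). A dip whose weighted region touches a window edge is
rejected rather than silently truncated. The estimator is exactly
translation-equivariant and invariant to uniform reflectance scaling.

**Instrument constants.** The bulk sensitivity S is the
finite-difference derivative of the centroid dip with respect to the
ambient index (default step 1e-3 RIU). The evanescent decay length δ is
evaluated from the bound-mode dispersion relation of the metal/ambient
pair, k_sp = k₀ √(ε_m n_a² / (ε_m + n_a²)), as δ = 1/Im(k_z,ambient).
Two conventions coexist in the literature: the field-*amplitude* decay
length (E ~ e^(−z/δ)) and the *intensity* decay length (half of it).
`decay_length` returns the amplitude length by default with an explicit
`convention` switch. The thickness equation, however, uses the intensity
convention: the first-order response to an adlayer weights the index
profile by the local field intensity |E|² ~ e^(−2z/δ_amp), so the
saturation factor is (1 − e^(−2d/δ_amp)) ≡ (1 − e^(−d/δ_int)). Using the
amplitude length in that exponent would bias recovered thicknesses by a
factor of two.

## Dual-wavelength thickness inversion

For a film of thickness d the ratio of responses at the two wavelengths
is modelled as

    R₁/R₂ = (S₁/S₂)(dn/dC₁ / dn/dC₂)(1 − e^(−d/δ₁))/(1 − e^(−d/δ₂)).

With δ₁ < δ₂ the thickness factor decreases strictly and smoothly from
δ₂/δ₁ (d → 0) to 1 (d → ∞), so a measured ratio inside the attainable
band inverts to a unique d; ratios outside the band (including the open
d → ∞ limit itself) raise an error that reports both bounds. Inversion
uses Brent bracketing (default bracket 1–500 nm, covering small-EV
diameters with margin) to a residual below 1e-10 relative. Uncertainty
propagates from the plateau standard deviations by the delta method
assuming independent responses. The refractive-index-increment ratio
dn/dC₁/dn/dC₂ defaults to 1.0 and must be measured for quantitative work
on materials with appreciable index dispersion between the two
wavelengths.

**Parameter calibration.** The closed-form δ neglects gold absorption
and the behaviour of the centroid estimator, and differs by ~2% from the
effective decay the full forward model exhibits for adlayers. Because
the ratio curve is shallow near EV-scale thicknesses, the inversion
amplifies parameter error roughly tenfold (the closed-form route biases
a 100 nm film by ~18%). `calibrate_dual_wavelength` therefore probes the
configured stack with a thin film (default contrast 1.5e-3, a typical
vesicle-film contrast) at two thicknesses and solves the saturation
model for effective (S, δ) per wavelength — the decay length exactly as
the instrument senses an adlayer. With calibrated parameters the
end-to-end simulate → process → invert round trip recovers diameters
across 80–120 nm within 0.7% (noise-free). The plateau ratio can be
formed from windowed means (default) or as the mean of frame-wise
ratios; the two differ only through noise weighting.

## Sequential layer fitting

One layer at a time is fitted by matching modelled to measured full
spectra at both wavelengths simultaneously: the free layer's thickness
is a single global parameter, its refractive index is independent per
wavelength, and the summed squared reflectance residual (equal weight
per wavelength by default; optional per-wavelength weights and peak
normalisation) is minimised by bounded trust-region least squares.
Starts are a fixed 3×3×3 grid over the search box, the best three
refined, ties broken by fixed ordering, so fits are deterministic.
Search boxes default to the published ranges: capture film d 80–120 nm
with n 1.334–1.335, corona slab d 1–10 nm with n 1.36–1.37. In a staged
experiment each stage's fitted layer is frozen into the stack before the
next stage is solved, so the corona estimate uses the capture signal as
its baseline and is independent of re-fitting the capture film; this
purity is asserted in the tests.

Thin slabs carry the classic d·(n − n_ambient) degeneracy. After each
fit the optimum is probed along that compensation ridge (d ± 10% with
the optical increment preserved); a residual flat to 1e-12 flags the
result as degenerate rather than reporting a spuriously precise pair.
A fit whose mean squared residual per point exceeds a threshold
(default 1e-7, suited to reflectance noise up to ~1e-4) is flagged
implausible; the sequential driver raises on such stages by default,
which is what catches stage/box mismatches such as permuted specs.
Non-convergence within the iteration budget is reported through a flag,
never as an exception; solutions pinned at a box bound emit a warning.

**Information limits.** At reflectance noise sd 1e-4 on the default
0.01° grid, Monte-Carlo recovery of corona slabs drawn from the
published box achieves a median thickness error of ~0.09 nm when the
corona is the only adlayer. Fitted on top of a 100 nm capture film the
same study yields ~0.22 nm — the evanescent field has decayed by
e^(−2·100/193) ≈ 0.35 at the corona's standoff, and the observed error
matches the Cramér–Rao bound of the three-parameter fit, i.e. it is an
information limit of the measurement, not an optimiser artefact.

## Sensorgram processing

Dip angles are extracted per frame, times and responses are re-origined
at the sample-injection instant (response at t_inj linearly interpolated
between frames), and the buffer control channel — which sees bulk
refractive-index changes but no binding — is linearly interpolated onto
the sample time base and subtracted, restricted to the overlapping time
range. No smoothing is applied anywhere. Plateau reads return the mean
and population sd over a time window; the averaging window is a required
analysis choice, not a hidden default.

## Synthetic experiments

`simulate_spr_experiment` renders a staged experiment — baseline,
capture injection, wash, plasma injection, final wash — through the full
optical model. Defaults are frozen at the study's conditions: stage
durations 120/600/600/900/900 s at 2 s frames; capture film 100 nm,
n 1.3345 (mid-box); corona 5.5 nm, n 1.365 (mid-box); a 5e-3 RIU bulk
index jump during the plasma stage (several hundred mdeg at the gold
sensor's sensitivity, as diluted plasma produces), removed at the final
wash while the corona remains. Layers grow by exponential saturation
(time constant 120 s) normalised to reach the stage truth exactly at the
stage end; the profile is a plumbing fixture, not a kinetic claim — no
mass-transport or Langmuir model is implied. Gaussian reflectance noise
is resampled when a draw leaves [0, 1], keeping the passive-medium bound
without clipping bias. The control channel receives bulk effects but no
binding layers. Every artefact embeds its scenario and seed and
regenerates bit-identically. Tests and the acceptance script run
coarser frame intervals (60–600 s) and, where appropriate, a 0.05°
angular grid; these are problem-size choices that leave the physics
unchanged, and the per-frame truth record makes any grid self-checking.

`simulate_proteomics` draws log2 intensities per protein from
N(20, 2²) — a typical reporter-ion log2 range — with replicate noise
σ = 0.25, two groups of three replicates, 10% of proteins shifted by
+1 log2 unit in the first group (sign-balanced shifts optional),
5% contaminants, and Bernoulli dropout with probability
sigmoid(15.5 − log2 intensity), i.e. ~4.5% of cells missing,
concentrated at low abundance — the missing-not-at-random structure the
downshifted-normal imputation assumes, at the low within-plex rate
characteristic of isobaric-label quantification. The dropout fraction's
analytic expectation (quadrature over the intensity law) is asserted
against the realised fraction.

What the generators do *not* emulate: instrument drift, bulk-index
decomposition beyond reference subtraction, EV polydispersity, spectral
interference, peptide-to-protein inference, between-plex batch effects.
Passing tests therefore demonstrate correctness of the analysis chain
under the stated physics and statistics, not robustness to every real
instrument artefact.

## Proteomics statistics

Filtering removes contaminant-flagged proteins and proteins lacking
≥ 3 valid values in *at least one* sample group (the stricter
every-group reading is a flag). Normalization divides each sample column
by its summed intensity and multiplies by the maximum summed intensity
across samples, equalising column sums; a per-group variant implements
the alternative reading of group-summed scaling. Note that
summed-intensity normalization presumes comparable total signal between
conditions: strongly one-sided regulation (many proteins shifted the
same way) biases all null proteins in the opposite direction, a known
property of this normalization family that the sign-balanced synthetic
scenario avoids.

Imputation operates on log2 intensities: missing cells in reference
column c receive draws from N(μ_c − 1.8 σ_c, (0.3 σ_c)²), the typical
abundance region of sub-detection values; the reference distribution is
the sample column by default (standard Perseus behaviour), per-protein
as a flag. Draws are reproducible by seed and present values are never
touched. A consequence worth knowing: a mid-abundance protein that loses
one replicate to dropout gets that cell imputed far below its own level,
inflating its within-group variance — detection power at effect
2 log2 units is ~0.97 on complete data but ~0.86 at the default 4.5%
dropout. This is the workflow's real behaviour, reported as such by the
acceptance script.

Differential enrichment uses two-sample t tests on log2 intensities
(pooled-variance Student by default, Perseus's default; Welch via flag),
log2 fold change as the difference of group means, and
Benjamini–Hochberg step-up adjustment (statsmodels) across all testable
proteins; proteins with zero variance in both groups are flagged
untested and excluded from the BH family. The significance line is
encoded exactly as adjusted (−log10) p ≥ 1.30, i.e. p_adj ≤ 10^(−1.30)
≈ 0.0501 — deliberately not a rounded 0.05. Set overlaps are exact;
top-N ranking sorts by mean intensity across a condition's replicates
with lexicographic accession tie-breaks.

The shipped `table2.tsv` transcribes the published 42-protein
differential-enrichment table as printed. Its "Adj. p value" column
exceeds 1 throughout and is consistent with −log10-transformed adjusted
p values; the file documents that interpretation without asserting it.
The printed sign bookkeeping (42 significant; 14 reduced, 28 increased;
12 rows bolded as absent from all nascent-vesicle sets) is reproduced
exactly by `table2_significance_counts`.

## Numerical choices

- Reflectance branch cuts: principal square root with the decaying
  branch enforced; inner-layer branch choice cancels analytically in the
  characteristic matrix.
- Root finding: Brent with xtol 1e-12; least squares: trust-region
  reflective with xtol/ftol/gtol 1e-14 and a 400-evaluation budget.
- Zero-thickness layers are optically inert and allowed, which lets
  staged simulations grow layers from zero without special-casing.
- Population (ddof 0) sd for plateau reads (a one-point window has
  sd 0); sample (ddof 1) sd for imputation reference estimates.
- Ties in multi-start ordering and in enrichment ranking are broken by
  fixed, documented orderings so every fit and ranking is deterministic.

## Known limitations

- The optical model is strictly planar and homogeneous: a captured
  vesicle layer is represented as a uniform slab (the "average diameter"
  reading), with no effective-medium mixing, roughness or anisotropy.
- Ratio-based sizing inherits the first-order assumption that the response
  is linear in the index contrast; very high-contrast films would need
  the full layer solver instead.
- Decay-length and sensitivity calibration are only as good as the
  configured stack; real instruments calibrate S from bulk standards,
  which the API accommodates by accepting measured parameters directly.
- The BH procedure controls FDR under independence/PRDS; strongly
  correlated protein families may exceed the nominal level.
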