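# Methods

This note documents the models, conventions, and numerical choices behind
`domseason`, and what the synthetic-data tests do and do not demonstrate.

## Hydrographic definitions

**Mixed layer depth.** The MLD is the shallowest depth below a reference
depth where potential density anomaly σθ exceeds its reference-depth value
by a threshold increment, with linear interpolation between the bracketing
samples. In the default *density* mode the increment is ρ·α(T_ref, S_ref)·ΔT
with ΔT = 0.2 °C and α, ρ evaluated from the one-atmosphere UNESCO 1983
(EOS-80) polynomial at the reference depth (α by a central finite
difference of the polynomial, half-width 10⁻³ °C). The reference depth
defaults to 10 m — common practice where the near-surface metre is noisy —
and is configurable. A *sigma* mode accepts a fixed σθ increment directly,
for users who standardize the threshold across profiles. When no crossing
exists the profile is flagged "fully mixed to the deepest sample". Adding a
constant to the whole σθ profile leaves the result unchanged.

**Chlorophyll layer.** The DCM is the depth of the profile maximum; the
DCML top and bottom are the interpolated depths nearest above/below where
fluorescence falls to a boundary fraction (default 0.35) of that maximum.
Boundaries never crossed are clamped to the profile ends and flagged; on a
degenerate plateau the first maximal sample wins.

**Seasons.** A four-state machine compares the MLD with the chlorophyll
layer: Stratified → FallTransition when the MLD first exceeds the DCML
top; FallTransition → Mixed when it exceeds the DCM depth; Mixed →
SpringTransition when it shoals back above the DCM; SpringTransition →
Stratified after the MLD has stayed above the DCML top for `persistence`
(default 2) consecutive observations. Two open design points are resolved
here: the fall/mixed onset is split at the DCM depth (the qualitative
definitions alone give both states the same trigger), and "rapidly
shoaled"/"remained above" are quantified by the persistence count, since
no rate threshold is available. Transitions cascade within one time step —
a monthly record can legitimately jump from Stratified past the DCML band
straight into Mixed. Missing layer data carries the previous label forward
with a warning.

**Oxygen.** Saturation concentrations use the Garcia & Gordon (1992)
refit of the Benson & Krause data, valid for T ∈ [−2, 40] °C and S ∈
[0, 42]; AOU = O₂sat − O₂obs. The volumetric basis (µmol L⁻¹, matching
bottle units) is default; the gravimetric fit value is converted with the
surface density. AOU at saturation is identically zero by construction.

**Zone integrals.** Depth is positive down; zones are half-open
[z_top, z_bottom) for discrete sample membership. Inventories are
trapezoidal integrals of linearly interpolated concentrations; 1 µmol L⁻¹
integrates to 1 mmol m⁻² per metre. Beyond the shallowest/deepest sample
the profile is extended as a constant and the integral flagged
(`ExtrapolationWarning`) — the MLD occasionally exceeds the deepest
bottle. Zone means come in two modes matching field convention:
inventory-normalized for concentration-type variables (DOC, TDAA, cell
counts) and discrete sample means for intensive variables (temperature,
DI, AOU, relative abundance).

## DOM quality

Replicate sets are screened by coefficient of variation: CV = s/x̄ with the
sample standard deviation, excluded when CV exceeds 0.20 strictly ("greater
than 20 %"); a zero mean with nonzero spread is flagged separately. TDAA-C
sums concentration × carbon atoms over the panel using standard molecular
formulas. Phenylalanine is excluded from composition work by default (it
co-elutes with an interferent in many seawater chromatograms and is a
minor mole fraction in oligotrophic gyres); its carbon can still be
included in TDAA-C on request.

The degradation index standardizes each amino acid's mole percent against
reference statistics and projects onto factor coefficients. The reference
table (AVG, STD, coefficient per amino acid) is an input, not a package
constant: published coefficient sets differ between data sets, and the
right choice belongs to the analyst. The packaged
`synthetic_reference_table()` spans the generator's two composition
endmembers and is labelled synthetic; it is for testing and for the
synthetic pipeline only. DI is linear on the standardized scale, invariant
to rescaling raw concentrations, and decreases when mole fraction shifts
from positively to negatively weighted amino acids.

## Conservative-mixing null model

For each analyte and consecutive time pair (t, t+1) both profiles are
integrated from the surface to the MLD at t+1. Under purely physical
mixed-layer homogenization (including entrainment as the layer deepens)
these two inventories are equal, so the pair falls on the 1:1 line. The
detector uses the signed perpendicular distance d = (I_next − I_prev)/√2
(the vertical difference differs only by the constant √2 and produces
identical z-scores), standardizes per analyte with the sample SD (small
per-analyte n), pools all z-scores, fits a normal distribution (mean, and
the square root of the unbiased variance — matching the usual
statistics-toolbox normal fit), and thresholds at its q-quantile (default
0.95). Flagging is two-sided by default — production above the threshold,
loss below its mirror image about the fitted mean — because losses are as
meaningful as productions; a one-sided mode reproduces the literal
single-quantile rule. Analytes whose distance spread is zero to within
floating-point residue of the inventory magnitudes (exactly conservative
tracers) are excluded as degenerate rather than divided by ~0.

The whole detector is invariant to the analyte's units, and its
false-positive rate under a noise-only simulation matches the nominal
quantile within binomial error (~10 % two-sided, ~5 % one-sided at
q = 0.95). DOC, TDAA-C, bacterioplankton abundance, and each targeted
metabolite run through the identical machinery.

The PERMDISP-style group-dispersion check (principal-coordinate embedding,
distance to group centroid, permutation F-test) is delegated to
scikit-bio's `permdisp` with a seeded permutation stream; the fully
degenerate case (each group a set of identical points) is short-circuited
to statistic 0, p = 1, where the F ratio is 0/0.

## Rates, flux, correlations

Rates are OLS slopes of zone-mean concentration against days since the
window start, reported in nmol L⁻¹ d⁻¹ with R² and n; the fitted change
over the window (Δ) is slope × duration. The annual convective export flux
uses the period-mean-difference mode: (mixed-season mean zone
concentration − other-season mean) × zone thickness, 1 µmol L⁻¹ = 10⁻³
mol m⁻³, reported per annual mixing event; the mode is recorded in the
output so alternative reconstructions (e.g. pre/post inventory
differences) remain comparable. How the original field estimate of this
flux was computed is not specified at this level of detail, so the mode
label is part of the result. Correlation matrices are Spearman rank
correlations on pairwise-complete observations (≥ 4 overlapping points),
with NaN for constant series.

`SARGASSO_RATE_TABLE` carries the published BATS 2016–2017 zone-rate
estimates as *inputs* for arithmetic consistency checks: the check passes
when Δ/duration lands within the combined rounding half-widths implied by
the two printed precisions. (Plain rounding of Δ/duration reproduces three
of the four printed rates exactly; the mesopelagic DOC row prints 30 while
4.0/136 d = 29.4, which is consistent only once Δ's own rounding interval
is honoured — hence the interval-overlap formulation.)

## Community response

ASVs unclassified at the class level (fewer than three semicolon-delimited
ranks, or an empty/unclassified class field) and chloroplast assignments
are removed before closing each sample to relative abundances. Enrichment
requires (1) the month of the ASV's maximal mesopelagic (120–300 m) mean
relative abundance to fall inside the mixing-and-aftermath window and (2)
its mixed-layer mean at maximal mixing to strictly exceed the pre-mixing
value — the second criterion rejects apparent increases produced purely by
entraining the surface population downward. Mixed-layer membership for
criterion 2 means samples shallower than that month's MLD.

The cross-correlation function pairs the response y(t) with the driver
x(t+k) on their pairwise-complete monthly overlap for k ∈ [−max_lag,
+max_lag] (gaps are left as gaps; interpolating a short monthly record
would fabricate data). Negative lag ⇒ the driver leads. Significance uses
the large-sample white-noise bound ±z₁₋α/₂/√n_k per lag (α = 0.05 default;
no detrending/pre-whitening by default). Responders are enrichment-passing,
non-cyanobacterial ASVs with a significant positive correlation at a
strictly negative lag against DOC and/or TDAA-C; the reported driver/lag is
the best significant negative-lag correlation. Mixing-window anomalies are
window mean minus all-time mean, judged against ±1 SD of the all-time
series.

## Synthetic water column

The generator is a monthly box model on a 0–500 m grid (5 m default):

* **MLD cycle** — flat at `mld_min` (20 m) when stratified; inside the
  mixing window the depth fraction ramps linearly from 0.25 to 1.0 of
  (mld_max − mld_min), so the first mixing month sits inside the DCML band
  (producing a Fall transition at monthly cadence) and the last reaches
  `mld_max` (242 m default) exactly, followed by an abrupt spring shoaling.
* **Hydrography** — temperature uniform above the MLD with a seasonal
  surface value, decaying below steeply enough that the density criterion
  recovers the prescribed MLD within one grid step; salinity constant;
  σθ from the EOS (stable by construction); a Gaussian DCM (95 m, 20 m
  width) homogenized during deep mixing; oxygen saturated in the mixed
  layer with AOU accumulating below.
* **Tracers** — instantaneous homogenization over the (grid-snapped) MLD
  each month, no diffusion below. Homogenization is defined to be exactly
  consistent with trapezoidal integration: mixed-layer nodes take the
  trapezoid mean of the layer and the first node below absorbs a
  compensating adjustment (the discrete analogue of the thin entrainment
  interface), so both the full-column inventory and any integral to the
  MLD are conserved to machine precision. Events add/remove an areal
  magnitude spread uniformly over the mixed layer (an extent below the
  MLD is an error). Optional linear zone trends superimpose euphotic
  production (+24 nmol L⁻¹ d⁻¹ DOC) and mesopelagic removal (−30 nmol L⁻¹
  d⁻¹) after maximal mixing — the non-conservative biology that the rate
  regressions recover, kept outside the conservative operator so its
  conservation contract stays exact. Measurement noise is applied last:
  mean-one lognormal factors with CV = `noise_cv` (default 0.12, matching
  10–20 % replicate CVs), independent per replicate/depth/month.
* **Amino acids** — total TDAA follows a surface-enriched conservative
  tracer; composition blends a fresh endmember (surface and newly mixed
  water) toward a glycine-enriched degraded endmember at depth, so DI
  decreases with depth and rises in the mesopelagic during export.
* **Community** — responder relative weight at month t is baseline +
  amplitude × D(t+lag) at depths in the responder's zone, with D the
  min-max-normalized mesopelagic DOC series; null taxa are stationary;
  a cyanobacterium is planted with responder-like dynamics so only the
  taxonomy rule can reject it, plus chloroplast and class-unclassified
  taxa for the screening filter. Counts are multinomial draws per sample
  (fixed sequencing depth), so relative abundances close to one exactly.

All randomness flows from the single configuration seed through named
child generators (`numpy` `default_rng([seed, tag, ...])`); identical
seeds give byte-identical fixtures and pipeline outputs.

Default planted lags are −1 and −2 months. Lags of −3 or −4 are valid
responder behaviour but not reliably recoverable under the selection rules
at monthly cadence: a taxon lagging ≥ 3 months behind a driver that only
begins rising mid-winter has not yet responded at maximal mixing, so the
mixed-layer enrichment criterion is decided by noise, and a −4 lag pushes
the abundance peak past the enrichment window entirely. Lag 0 is excluded
by the strictly-negative-lag rule.

**What the synthetic tests do not show.** The generator has no
sub-monthly variability, no lateral advection or eddies, no diffusion
below the mixed layer, no irregular multi-cast sampling, Gaussian-like
noise without instrument drift, and a single dominant driver per
responder. Passing tests demonstrate that the estimators recover their
own model's ground truth at realistic noise levels — not that the field
record satisfies these assumptions.

## Problem sizes and runtime

The validation studies are sized for desk-scale runs: 45 noise-only
tracers × 23 monthly intervals (1035 analyte-intervals) for null
calibration, 50 injected events over 26 months for sensitivity, a 26-month
driver for lag recovery, and a 15-month community with 3 responders,
20 null taxa, and the three screening taxa for selection. The full test
suite and the acceptance script each complete in well under a minute.

## Known limitations

* EOS-80 rather than TEOS-10; at the precision of a 0.05 kg m⁻³ MLD
  increment the difference is immaterial, and the sigma-increment mode
  sidesteps the choice entirely.
* The MLD is snapped to the nearest depth-grid node inside the tracer
  simulator; fractional MLDs in the observation pathway therefore carry a
  ≤ half-grid-step representation mismatch (~0.1 % inventory), far below
  replicate noise.
* The one-sided flagging mode labels only upper-tail exceedances; whether
  losses should use the mirrored quantile or the absolute value is an
  analyst's choice exposed as `sidedness`.
* Monthly binning by calendar month; irregular multi-cast months are
  averaged, not modelled.
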