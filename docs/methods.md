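# Methods

This note documents the models, numerical choices and known limitations of
guvmech, and what the synthetic generators do and do not emulate.

## Aspiration mechanics

The aspirated vesicle is modelled as a spherical outer segment (radius
*R*<sub>v</sub>) joined at the pipette mouth (inner radius *R*<sub>p</sub>) to
a tongue consisting of an open cylinder of length *L*<sub>p</sub> −
*R*<sub>p</sub> and a hemispherical cap. The outer segment is the **major**
spherical cap of height h = *R*<sub>v</sub> + √(*R*<sub>v</sub>² −
*R*<sub>p</sub>²), giving area 2π*R*<sub>v</sub>h and volume (πh²/3)(3*R*<sub>v</sub>
− h). States with *L*<sub>p</sub> < *R*<sub>p</sub> (sub-hemispherical
tongues) are rejected rather than modelled — they sit outside the measurement
regime of a tension-controlled aspiration experiment.

Tension follows the Laplace relation τ = ΔP·*R*<sub>p</sub>/(2(1 −
*R*<sub>p</sub>/*R*<sub>v</sub>)) (units: Pa, µm in; mN/m out). Area strain is
referenced to the first analysed step, taken after prestressing, so the
intercept of the tension–strain line carries no physical meaning and is left
free in the fit; forcing the line through the origin would bias
*K*<sub>A</sub>.

**Geometry inversion.** `solve_geometry(area, volume, rp)` finds
*R*<sub>v</sub> by bracketed root finding (Brent, xtol 1e-14) on the area
residual; for each trial *R*<sub>v</sub> the tongue length follows linearly
from the volume constraint. The admissible bracket is scanned on a 256-point
grid between *R*<sub>p</sub> and the radius of the area-equivalent sphere and
the sign change with the largest *R*<sub>v</sub> (the near-spherical branch)
is refined. For very small *R*<sub>p</sub> the tongue volume is a difference
of near-equal numbers, so the *L*<sub>p</sub> ≥ *R*<sub>p</sub> feasibility
check uses a cancellation-aware tolerance ~ε·V/(π*R*<sub>p</sub>²).

**Error propagation** is first-order with numeric central differences
(relative step 1e-6) rather than hand-derived partials; this matches the
differential error budget while avoiding transcription mistakes. The α error
budget treats the reference-step geometry and the shared pipette radius
jointly through a five-variable Jacobian.

## Image analysis

Coordinates are 0-based pixel indices with pixel centres at integers, x
rightward, y downward; the tongue lies on the low-x side of the pipette-mouth
plane. One ROI per series replaces per-frame manual selection — the same
information, automated. Radius measurement selects the brightest 1, 2 and 3 %
of ROI pixels (ties broken in row-major order for bit-reproducibility), fits
each set with the Taubin algebraic circle fit (moment formulation, Newton on
the characteristic polynomial; exact for co-circular points), and averages
the three radii. The radius uncertainty is the sample SD of the three radii
floored at half a pixel, since a three-sample SD can degenerate to zero.

At 0.2 µm/px this selection-based estimator has an irreducible pixel-aliasing
wiggle of ~±0.015 px in the recovered radius as the true radius drifts
through the grid; this, not intensity quantisation, is what limits noise-free
*K*<sub>A</sub> recovery to a few per cent.

**Tongue tip.** Columns in a band of half-width *R*<sub>p</sub>/2 around the
pipette axis are scored by their three brightest pixels. Peak, background and
threshold decisions run on a lightly smoothed profile; the tip is then
refined by least squares on the raw Gaussian leading edge (the log of the
background-subtracted score is exactly quadratic in x for a Gaussian line
spread). When the membrane line-spread σ is known the fit has two free
parameters (amplitude, tip position); the pipeline self-calibrates σ per
frame from the intensity-weighted second moment of the vesicle ring's radial
profile. The reported *L*<sub>p</sub> uncertainty is one pixel.

**K_A regression.** `ElasticityModel` fits the tension–strain line after
excluding points below `tau_min` (default 0.5 mN/m, the conventional
enthalpic-regime cutoff; configurable). The default orientation regresses α
on τ and reports *K*<sub>A</sub> as the inverted slope: the tension derives
from the controlled suction pressure and is orders of magnitude more precise
than the image-derived strain, and a conventional τ-on-α fit suffers
regression dilution (tens of per cent at snr = 5) when the noisy variable
sits on the abscissa. The conventional orientation (WLS of τ on α with
weights 1/στ²; α errors never used as weights) is available as
`orientation="direct"`; the two agree exactly on noise-free data. Standard
errors come from the regression covariance (delta method for the inverted
slope), which the simulation tests show gives ≈95 % two-SE coverage.

`hysteresis_check` interpolates α(τ) linearly on the ascending and descending
branches over their common tension range and reports the maximum |Δα|
(default pass threshold 0.002).

## Fluorescence quantification

Membrane intensity is the mean over a 5-pixel-thick ring on the fitted
contour (|d − r| ≤ 2.5 px) minus the mean interior intensity, with the
interior sampled at d < r − 5 px — the guard band keeps membrane
bleed-through out of the background estimate, mimicking manual interior
sampling away from the contour. Dithionite reaches only the externally
exposed leaflet, so the post/pre net-intensity ratio classifies dye
sidedness. The thresholds quantify qualitative outcomes (half / complete / no
quench): ratio < 0.15 → outer leaflet only, 0.35–0.65 → both leaflets,
> 0.85 → inner leaflet only, otherwise indeterminate; they partition [0, ∞)
and are scale-invariant. Group comparisons use the ratio of median net
intensities with a seeded 10,000-resample bootstrap percentile CI.

## Bilayer metrics

Leaflet membership comes from explicit per-atom tags (chain ID in PDB input),
never from the sign of z, so noisy or displaced frames remain well defined.
Before any metric, z is wrapped into the box and re-referenced to the
mass-weighted circular mean of the lipid atoms, making all metrics invariant
under rigid z-translation. The default bin width is 0.1 nm — fine enough for
nm-scale features at negligible cost.

*h*<sub>PP</sub> is the per-frame difference of mean phosphorus heights,
averaged over frames with SEM. Density profiles are mass histograms divided
by *L*<sub>x</sub>*L*<sub>y</sub>·Δz, averaged over frames; mass is conserved
exactly by construction. Interdigitation integrates
4ρ<sub>u</sub>ρ<sub>l</sub>/(ρ<sub>u</sub>+ρ<sub>l</sub>)² by the trapezoid
rule over bins where ρ<sub>u</sub>+ρ<sub>l</sub> > 0; for identical leaflet
profiles the integrand is 1 on the support, so the width equals the support
length (to one bin).

The fluctuation estimator *K*<sub>A</sub> = k<sub>B</sub>T⟨A⟩/Var(A) (unbiased
sample variance, ≥10 samples) is a deliberately simple box-area surrogate for
leaflet-resolved real-space fluctuation methods, which require per-lipid
areas this package does not compute; it is exact for Gaussian equilibrium
area fluctuations but ignores time correlation in real trajectories.

## Statistics

Weighted summaries use w<sub>i</sub> = 1/σ<sub>i</sub> — inverse **error**,
not inverse variance — as the convention stated with the source data; the
conventional 1/σ² is available via `weight_power=2`. The weighted SD uses the
frequency-weight denominator Σw. Kruskal–Wallis is implemented from its
rank-sum definition with mid-ranks and tie correction; the p-value uses the
χ² approximation with k−1 degrees of freedom, adequate for the group sizes
here (≥10) — no exact permutation p is computed. When all pooled values are
identical the tie-correction denominator vanishes and H is defined as 0 with
p = 1. Post-hoc comparisons are Dunn's z-tests on pooled mid-ranks with the
same tie term, Holm-adjusted — the standard nonparametric follow-up when no
specific method is mandated.

## Synthetic data: what it emulates, and what it does not

The aspiration generator inverts the analysis chain: for each suction
pressure it solves the self-consistent (τ, α, *R*<sub>v</sub>,
*L*<sub>p</sub>) state at constant vesicle volume for a prescribed
*K*<sub>A</sub>, then renders the contour (outer arc, pipette walls,
tongue-tip half-ring) with a Gaussian line spread and shot-noise-like
Gaussian noise whose variance is proportional to local intensity, scaled so
peak/σ = snr. Distances to the contour are computed analytically, so the
rendered profile is exact to machine precision. Defaults: a 10-µm GUV
(area 4π·100 µm², volume 97 % of the equivalent sphere — a mildly deflated
vesicle with a visible tongue), *R*<sub>p</sub> = 3 µm, ten pressure steps
from 250 to 3000 Pa spanning tensions ≈0.5–6.5 mN/m (the enthalpic regime),
0.2 µm/px on a 512×512 canvas, line-spread σ = 1.5 px, peak 3000 counts over
a 5 % background. Not emulated: optical PSF physics, pipette-wall thickness,
vesicle drift, bleaching, out-of-focus light. Passing recovery tests
therefore demonstrates correctness of the measurement chain, not robustness
to every optical artefact of real confocal data.

The bilayer generator places one phosphorus atom per lipid at ±*h*<sub>PP</sub>/2
with Normal(0, σ<sub>z</sub>) jitter and 16 chain pseudo-atoms per lipid
drawn uniformly between the phosphorus plane and the far edge of the overlap
region, so the two leaflets' chain distributions overlap over exactly the
prescribed width; per-lipid masses sum to a POPC-like 760 amu (fixed so
density magnitudes are reproducible), octane molecules are single 114.23-amu
pseudo-atoms centred at the midplane (σ = 0.35 nm). Default system size
mirrors the simulated membranes: 324 lipids per leaflet. No force-field
realism, no lateral structure, no water/ions.

The population generator draws per-vesicle values Normal(mean, sd) with a
constant per-vesicle error scale per group — plumbing for the statistics
module, not a model of vesicle-to-vesicle variability.

## Problem sizes

Default validation sizes — 10 pressure steps per series, 20 noisy replicates
per modulus, 20 bilayer frames of 324 lipids/leaflet, 5000-sample area
series, 1000-seed null calibration — were chosen so every documented
recovery is measured at comfortable statistical resolution on a laptop-scale
run.

## Known limitations

* The selection-based radius estimator carries a ~0.015 px aliasing wiggle;
  at 0.2 µm/px this bounds noise-free *K*<sub>A</sub> recovery at a few
  per cent. Finer sampling or intensity-weighted fitting would reduce it.
* α measurement errors are reported but not used as regression weights; the
  inverse orientation removes the attenuation bias but per-point
  heteroscedasticity is ignored.
* The fluctuation *K*<sub>A</sub> assumes uncorrelated area samples.
* The quench classifier is threshold-based; no kinetic model of the
  quenching reaction is attempted.
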