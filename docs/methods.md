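# Methods

This note documents the models, estimators and numerical choices behind
`seedhydro`, and what its synthetic-data verification does and does not
demonstrate about real measurements.

## Pressure–volume curves

**Model.** A dehydrating leaf sample is described on the reciprocal
scale: plotting 1/Ψ against water saturation deficit
WSD = (TW − FW)/(TW − DW) separates a curved turgescent section from a
linear osmotic section. The osmotic section follows from the
Boyle–van't Hoff relation Ψ_π = Ψ_osat/R_s (R_s = relative symplastic
water content), which is exactly linear in 1/Ψ vs WSD; the turgescent
section adds turgor pressure and is fitted empirically with a parabola.

**Estimator.** `fit_pv_curve` performs an exhaustive split search: for
every admissible boundary k (≥ `min_segment` = 3 points per side,
configurable) it fits a quadratic to points 1..k and an OLS line to
k+1..n on the reciprocal scale and picks the split minimising pooled
RSS. Ψ_TLP is the real root of quadratic − line nearest the split
midpoint (accepted inside a one-point-widened bracket so noise cannot
push a genuine intersection just outside the boundary pair); Ψ_osat is
the back-transformed line intercept at WSD = 0. If the best split's
fits do not intersect, splits are retried in RSS order, then the
closest-approach point of the best split's fits inside the bracket is
used; only if all of that fails is a fit error raised with diagnostics.
This keeps the procedure deterministic with no manual section picking.

**Modulus of elasticity.** ε is the OLS slope of turgor pressure
Ψ_P = Ψ − Ψ_π(WSD) against relative water content over the turgescent
points, with Ψ_π back-transformed from the fitted osmotic line
(`epsilon_mode="turgor"`, default). The literature is not uniform on
the regressor; the slope of raw Ψ vs RWC is available as
`epsilon_mode="raw"`. Note that when an apoplastic water fraction a is
present, the slope against *total* RWC overestimates the symplastic
modulus by the factor 1/(1 − a); the generator's exported `epsilon`
truth refers to the symplastic definition.

**Pooling.** Two samples of the same species × age class are pooled by
normalising each to WSD with its own turgid/dry weights before merging
and re-sorting — pooling raw weights would mix weight scales. The
operation accepts > 2 samples but warns, since the measurement protocol
pools exactly two.

**Generator and its realism.** `gen_pv_series` samples the symplastic
model at `n_points` = 16 decreasing water contents, half on each side
of the turgor-loss point, with Gaussian noise on Ψ only (psychrometer
error dominates balance error at 0.1 mg resolution). The first point is
placed where Ψ = 0.5·Ψ_TLP and the last where Ψ = 2·Ψ_TLP. The starting
point matters: psychrometer series begin on mildly dehydrated tissue
(first readings around −0.4 to −0.6 MPa), and in that regime the
turgescent section is well approximated by a parabola in reciprocal
space. Sampling from near full saturation instead makes 1/Ψ strongly
hyperbolic (it diverges as Ψ → 0) and biases the parabola–line
intersection by ~0.08 MPa; this is a property of the fitting model, not
of the code. Noise-free recovery is exact for Ψ_osat and within
0.006 MPa for Ψ_TLP; at σ_Ψ = 0.03 MPa the median absolute errors over
100 replicates are ≈ 0.016 (Ψ_osat) and ≈ 0.028 MPa (Ψ_TLP). Real
curves add oversaturation plateaus and rehydration artifacts that the
generator deliberately omits; passing recovery tests therefore shows
the estimator is unbiased under the assumed model, not that field
curves are free of such artifacts.

## Evaporative-flux conductance

Flow is the mean of interval-wise mass-loss rates converted with the
molar mass of water (0.018015 g mmol⁻¹); this equals
(first − last)/span for equal intervals but keeps per-interval rates
for the steadiness test. Steadiness is a two-sided OLS slope test of
interval rates against time (α = 0.05, configurable); only a
significant *decrease* flags non-steady flow, and flagged series are
kept, not discarded. K_shoot = F/|Ψ_plant| — the source potential in
the tube is ≈ 0, so the driving gradient is the magnitude of the plant
potential and conductances are reported positive. K_shoot_L divides by
leaf area.

Traits that exist only at group level (Huber value, xylem-area-specific
conductance) are ratios of group means with first-order (delta-method)
error propagation: se = |r|·√(cv_num² + cv_den²). Against a 10⁵-draw
parametric bootstrap this agrees to ≈ 3% at component CVs around 0.1
(the regime of the group summaries it is applied to) but degrades to
> 10% once the denominator CV exceeds ≈ 0.2, where the ratio
distribution becomes heavy-tailed — a known limitation of first-order
propagation, retained because it is the convention for these traits.
Group differences for such traits use a Welch test on the summary
statistics with Welch–Satterthwaite degrees of freedom computed from
the squared SEs and group sizes.

## Acoustic-emission embolism resistance

Events below 35 dB are discarded (threshold inclusive). Activity is
counted in half-open 300-s bins anchored at the first retained event —
an event exactly on a boundary belongs to the later bin — so total
counts are conserved. Each bin takes the water potential interpolated
linearly between anchor measurements at the bin midpoint; beyond the
anchor span the potential is clamped to the end values with a warning,
never extrapolated.

Smoothing is Savitzky–Golay with window 11 bins and order 3 by default
(both configurable; the window shrinks to the largest valid odd length
for short series, and series shorter than order + 2 are flagged and
left unsmoothed). Peaks of the smoothed activity are local maxima with
prominence ≥ 0.1 × the smoothed maximum, ranked by prominence;
Ψ_AEAmax is the most prominent one, with smaller peaks retained for
reporting. When activity rises monotonically into the final bin — the
near-linear emission increase at low potentials from non-conductive
tissue, typical of angiosperms — the endpoint is not a candidate and
only becomes the answer if no interior maximum exists; a pure
global-maximum mode is available by flag.

**Generator.** Each of 500 conduits draws a cavitation threshold from
N(mode, 0.3 MPa) truncated to negative values (a Weibull is the
vulnerability-curve convention, but the truncated normal has a
closed-form mode, which is the recovered quantity) and clicks once when
Ψ(t) first crosses it. Ψ(t) decays exponentially from −0.5 MPa toward
an asymptote 1.5 MPa below the mode over 6 h (τ = 2 h), anchors every
30 min; amplitudes are N(45, 8) dB so a realistic fraction falls below
the 35 dB cut; background events form an inhomogeneous Poisson stream
whose rate rises linearly as Ψ falls (peak 0.02 s⁻¹). Because the
dehydration rate |dΨ/dt| shrinks over time, the activity peak sits
slightly above the threshold mode (analytically ≈ +0.06 MPa for these
settings); recovered medians over 50 seeds are within 0.06 MPa of the
mode for modes −1.5 to −4.0 MPa. The generator does not model event
clustering, sensor detachment or multi-click conduits.

## Xylem anatomy

A_xyl averages the four directional diameters first and then applies
the annulus formula π/4·(d̄²_X+P − d̄²_P); averaging per-direction areas
instead is available for sensitivity checks. Conduit diameters assume
square sections for conifer tracheids and circular for angiosperm
vessels; diameter→area round-trips are exact. d_h = Σd⁵/Σd⁴ weights
conduits by their flow contribution and always lies between the
arithmetic mean and the maximum. To avoid over-weighting individuals
with many measured conduits, all conduit-level traits are averaged per
individual before group averaging; d_max is the maximum over
per-individual maxima. (t/b)² is averaged per section, then
hierarchically.

**Huber value scale.** The published group table prints HV with a
×10⁻⁶ m² m⁻² header, but recomputing mean A_xyl/mean LA from the same
table reproduces the printed numbers only on a ×10⁻⁴ scale
(0.366 mm² / 4.17 cm² = 8.78 × 10⁻⁴). The implementation computes the
raw dimensionless ratio and applies a configurable display scale
defaulting to 10⁻⁴, the internally consistent convention.

## Cohort statistics

Raw-value traits are screened with Shapiro (recorded) and Levene
(routing): homogeneous variance → Tukey HSD, otherwise Games–Howell;
α = 0.05 throughout. Pairwise significance is collapsed to a compact
letter display by insert-and-absorb, and every display is checked by an
exhaustive verifier (groups share a letter iff not significantly
different) — the verifier runs in the test suite on hundreds of random
significance graphs. Summary-only traits route to all-pairs Welch tests
on (mean, SE, n).

Lineage aggregates are the mean and *sample SD across species means* —
deliberately distinct from the per-group SEs across individuals printed
in tables; the two conventions are never mixed. Correlations are
Pearson r over species × age group means, for all species together and
per lineage, with stars at 0.05/0.01; constant vectors report missing r
rather than 0.

## Problem sizes and determinism

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`; the pipeline writes byte-identical outputs
on reruns with the same inputs. Verification sizes were chosen as the
smallest that make the Monte-Carlo bands stable: 100 replicates for PV
recovery at σ_Ψ = 0.03 MPa, 50 seeds × 3 threshold modes for acoustic
recovery, 1000 random populations for the d_h oracle, 10⁵ draws for the
ratio-SE bootstrap. `scripts/acceptance.py` re-derives every headline
quantity from scratch in a few seconds.

## Known limitations

- The PV fit assumes a single clean transition; curves with
  oversaturation plateaus or rehydration artifacts are out of scope.
- First-order ratio-SE propagation is inaccurate for denominator
  CVs ≳ 0.2 (see above).
- Ψ_AEAmax is a peak-activity proxy, not a percent-loss-of-conductance
  threshold; no Weibull vulnerability curve or P50 is fitted.
- The generators reproduce the statistical structure the estimators
  assume, not xylem network mechanics; recovery results quantify
  estimator behaviour under those assumptions only.
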