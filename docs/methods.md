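# Methods

This note documents the models, estimators, numerical choices and known
limitations of `speckledyn`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## The physical picture

Coherent X-rays scattered by a granular, hydrated protein sample produce a
speckle pattern whose temporal fluctuations encode the sample's nanoscale
dynamics. In the regime the package addresses, the beam itself stimulates
collective stress–relaxation: the measured relaxation rate is the sum of
an equilibrium rate and a beam-driven term linear in the incident flux
density,

    1/τ = 1/τ0 + a·F,

with τ0 the equilibrium time constant, `a` the beam-coupling constant
(μm²/ph) and F the flux density ((ph/s)/μm²). The decorrelation is
*ballistic*: the rate is linear in the momentum transfer Q and the
intensity correlation is a compressed exponential,

    g2(Q, t) = β · exp[−2 (t/τ)^α] + c,        α ≈ 1.5,

where β is the speckle contrast and c the baseline. On cooling, τ0
follows an Arrhenius law τ0(T) = A·exp(E_a/RT); near T ≈ 227 K the KWW
exponent dips below 1 and the two-time correlation function develops
pronounced fluctuations, quantified by the dynamic susceptibility χ_T —
the signature of collective dynamical heterogeneity.

## Conventions

* **Siegert factor.** The exponent "2" is kept explicitly inside the KWW
  form, so the *field* correlation is `exp[−(t/τ)^α]` and a fitted τ is
  directly comparable with a generator τ. Generators and fitters share
  this convention throughout; results from software using
  `β exp[−(t/τ)^α]` differ by `τ → τ·2^{1/α}`.
* **Normalization.** Both g2 and the TTC use the symmetric (two-mean)
  normalization `⟨I(t0)I(t0+t)⟩ / (⟨I(t0)⟩⟨I(t0+t)⟩)`, which reduces to
  the single-squared-mean form under stationarity and is less biased under
  slow drift.
* **Q computation.** Exact `Q = (4π/λ)·sin(θ)` with `2θ = arctan(r/SDD)`;
  no small-angle approximation (negligible cost, one less validity
  boundary). Pixels are indexed 0-based `(row, col)` from the top-left;
  the beam center uses the same convention and may lie off-detector.
  λ = 1.23984193/E(keV) nm.
* **Units.** Temperatures in K, times in seconds at every API boundary
  (frames only inside the generators), Q in 1/nm, flux density in
  (ph/s)/μm², E_a in kJ/mol with R = 8.314462618 J/(mol·K).
* **Q bins.** Default 30 log-spaced bins over the populated range;
  analysis annuli are disjoint rings of fractional width 10% around the
  target centers (0.08 and 0.1 1/nm in the study configurations). Bin
  intervals are half-open `[lo, hi)`.

## Synthetic generators

Two independent generative routes exist so that each validates the other
and no estimator is ever tested against its own model assumptions.

**Physical route (Lévy scatterers).** Each pixel is an independent
realization of `E(t) = Σ_j exp(i q x_j(t))` over point scatterers whose
velocities are drawn from a symmetric Lévy-stable law of index μ ∈ (0, 2]
and scale c (the stable characteristic function gives the field
correlation `exp[−(c q t)^μ]` exactly, so the KWW exponent equals μ, the
rate `1/τ = c·q` is linear in Q, and τ is calibrated analytically via
`c = 1/(q τ)`). Positions advance ballistically between Poisson-timed
velocity redraws ("stress-release events"); at high event rate the decay
crosses over to a simple exponential with rate
`(cq)^μ λ^{1−μ} Γ(1+μ)` — a closed-form check exercised in the tests.
Lévy draws are truncated at the 1−10⁻⁶ two-sided quantile to avoid phase
overflow; this is a controlled bias of order 10⁻⁶ in tail mass.
Intensities sum M independent mode realizations (speckle contrast
β = 1/M) and are Poisson-sampled at the configured count rate.

**Statistical route (Gaussian-field oracle).** Stationary circular complex
Gaussian processes with autocorrelation `exp[−(t/τ)^α]` are drawn by
circulant spectral embedding (the stretched exponential is positive
definite for α ≤ 2; embedding length 4× the series, doubled once on a
negative-eigenvalue failure, then a hard error). The expected g2 is
`1 + β exp[−2(t/τ)^α]` exactly, independent of any scatterer model.

**Heterogeneity.** Dynamical heterogeneity is modeled as a two-state
telegraph process shared by all pixels of a stack (the switching must be
collective to survive pixel averaging and appear in the TTC). In the
standalone two-state configuration the states realize the absolute
fast/slow pair (26 s / 220 s at full strength, τ centred on their
geometric mean). In temperature scans the telegraph modulates τ(T)
multiplicatively by `g^{±A(T)}` with `g = sqrt(τ_slow/τ_fast)`, preserving
the geometric mean; the strength A(T) ∈ [0, 1] is a Gaussian bump peaked
at the anomaly temperature (width 8 K). The Gaussian profile and the
telegraph process itself are modeling choices — the simplest stationary
constructions producing an interior χ_T maximum — not measured facts.
Telegraph switching rates default to mean episodes of 300 s (fast) and
800 s (slow), i.e. episodes long enough to express their relaxation time
yet frequent enough that a scan-length stack samples ~10 switching cycles.

**Frame stacks.** Rendered stacks place independent pixel ensembles on the
annuli of a compact synthetic detector (96×96 pixels, distance shortened
so the 0.05–0.15 1/nm rings fit); each ring subsamples to the configured
pixel count, everything else is dark and masked. Geometry always comes
from configuration, never from data. Identical config + seed produces
bit-identical stacks (seeds fan out through `numpy.random.SeedSequence`).

**Study conditions.** The generator defaults are the study's conditions:
unattenuated flux density 4.4×10⁶ (ph/s)/μm² with attenuations
0–90%; temperature grid {290, 270, 250, 240, 230, 225, 220, 210, 195,
180} K at F = 1.5×10⁶; ground truths τ0 = 336 s, a = 1.1×10⁻⁸ μm²/ph,
A = 1.8 s, E_a = 9.4 kJ/mol, anomaly at 227 K, fast/slow pair
26 s / 220 s; hydration level h = 0.28 carried as sample metadata.

## Estimators and their errors

**Lag grid.** The default lag scheme is a multi-tau-style grid (16
channels per level, spacing doubling per level), but correlations are
always evaluated *exactly* at those lags by an O(N·n_lags) sweep — no
per-level intensity pre-averaging. This removes the classic multi-tau
pre-averaging bias and makes the vectorized estimator agree with the
brute-force reference correlator to 10⁻¹² relative, which the tests
enforce. At desk scale the exact sweep costs well under a second.

**g2 errors.** Pixels of a Q annulus are independent speckle realizations,
so errors come from jackknife over pixels. Because neighbouring lags share
the underlying data, a least-squares fit that treats g2 points as
independent understates parameter errors by a factor of ~3; `fit_kww`
therefore refits delete-one-group jackknife replicates of the curve (10
pixel groups) and reports the jackknife covariance of the fitted
parameters. This calibration matters downstream: the weighted Arrhenius
fit is only stable when the low-temperature points carry their true
(large) uncertainties.

**Flux correction before the Arrhenius fit.** The measured rate at finite
flux is `1/τ = 1/τ0 + a·F`; the temperature-scan analysis subtracts the
configured `a·F` (delta-method errors) and fits `ln τ0` against 1/T.
Without this step the beam-driven term (a·F ≈ 0.0165 1/s at the scan flux)
compresses the observed τ range to ~36–57 s and no activation energy is
recoverable; with it, recovery is unbiased. The subtraction amplifies
relative noise by (τ0/τ)² at the coldest points, which the weighted fit
absorbs; points whose corrected rate is non-positive are dropped with a
warning. In a full experimental campaign `a` would come from the flux
experiment; in the synthetic study it is read from the generator metadata.

**Time-axis collapse.** Under the coupling model
`τ(F) = τ0/(1 + a F τ0)`, multiplying the lag axis by `(1 + a F τ0)`
equals `t/τ(F)` up to the constant τ0 and collapses the flux family onto
one master decay (an F = 0 curve keeps its axis). The collapse score is
the maximum spread of the normalized decays `(g2−c)/β` across curves on a
common log-lag grid, to be compared with the pooled interpolated error.

**χ_T.** For each δt, χ_T is the ddof-1 variance of `C(t, t+δt)` along
the TTC diagonal, divided by β² (configurable: `none | mean² | β²`;
division by β² makes χ comparable across temperatures and contrast modes,
and the normalization mode is recorded in every output). Errors come from
a block bootstrap over contiguous diagonal segments, since switching makes
diagonal samples strongly correlated. TTCs are computed at full frame
resolution up to 4000 frames and window-averaged beyond (window recorded).
A homogeneous process leaves only a finite-sampling floor ∝ 1/n_pixels,
which shrinks monotonically with problem size (tested at three sizes).

**χ₀(T) peak.** χ₀ is the maximum of χ_T over δt (ties to the smaller δt;
boundary maxima flagged). The peak temperature comes from a Gaussian-bump
fit of χ₀(T) (baseline + peak); on the uneven default grid a 3-point
parabola through the argmax carries a systematic ~2–3 K bias toward the
nearest coarse grid point, while the bump fit recovers the configured
anomaly within ~1.5 K across seeds — the parabola and the discrete argmax
remain as fallbacks. A peak is called significant when max/median ≥ 2.

**α(T) dip.** Fitted as `α(T) = α_base − depth·exp[−(T−T_min)²/(2w²)]`
with weighted least squares; significance requires both depth > 2 SE and
decisive AIC preference (Δ > 10) over a flat α(T) — the depth criterion
alone misfires on smooth noise. Non-convergence falls back to the discrete
argmin (ties toward lower temperature) flagged not significant.

**Fast timescale at the χ_T peak.** Non-overlapping diagonal windows of
width 4×δt_peak are ranked by how far their mean `C(t, t+δt_peak)` falls
*below* the diagonal mean — the fast side of the variance peak — and the
most decorrelated half is kept. Each kept window's diagonal-averaged
local g2 is KWW-fitted with the baseline fixed at 1, and the *median* of
the window time constants is reported: windows straddling an episode
boundary produce intermediate values that would bias a mean by ~30%,
while the median recovers the fast constant within a few percent. This
construction is one defensible reading of "the relaxation time of the
epochs at the χ_T peak"; the underlying experimental extraction is not
uniquely defined.

**Contrast.** Default: linear extrapolation of g2 − 1 over the first four
lag channels to t = 0. Alternative: per-frame normalized pixel variance
corrected for Poisson noise, `var(I)/⟨I⟩² − 1/⟨I⟩`; an estimate not
significantly above zero (β < 2 SE) is refused as unresolvable.

## Problem sizes

The recovery experiments use, per run: flux family — 6 flux levels ×
4000 frames × 100 pixels, pooled over 5 seeds (τ0 and a are pooled at the
regression-coefficient level, since 1/intercept is a skewed transform and
a 5-seed scatter SE is χ²-noisy; the reported SE is the larger of the
scatter and the propagated per-fit errors); Arrhenius scan — 10
temperatures × 6000 frames × 150 pixels, pooled over 3 seeds the same way;
ballistic exponent — 20000 frames × 200 pixels at four Q; anomaly scan —
10 temperatures × 6000 frames × 100 pixels, with the T_min and T_peak
estimates averaged over 3 seeds (single-scan localization scatters by
~2 K because only three grid temperatures sample the dip); two-state run —
6000 frames (2 s spacing) × 100 pixels. These sizes put every estimator comfortably in
its working regime while a full acceptance pass completes in under two
minutes on one core.

## What the synthetic study does and does not show

The generators emulate the statistical structure the estimators rely on:
Gamma-distributed multi-mode speckle with Poisson counting noise, KWW
field correlations with exact ground truth, ballistic Q scaling, flux
coupling, Arrhenius kinetics, and collective two-state switching. They do
**not** simulate protein grains, hydration water, radiolysis chemistry,
beam heating, detector artifacts beyond Poisson noise, spatial speckle
correlations (pixels are independent realizations — adequate because all
implemented estimators average over pixels), WAXS structure, or
non-stationary aging beyond the telegraph process. Passing recovery tests
therefore demonstrates the correctness and calibration of the analysis
chain under the stated statistical model, not the physics of any real
sample; on experimental data the error model (independent pixels) and the
two-state picture are approximations to be validated case by case.

## Known limitations

* α is bounded to (0.2, 3]; decays slower than the lag span are flagged
  "unresolved decay" rather than extrapolated.
* The χ_T bootstrap underestimates errors when fewer than ~5 switching
  episodes fit in a stack; the scan defaults keep ~10.
* `correct_rate_for_flux` silently loses temperatures whose dynamics are
  indistinguishable from the purely beam-driven limit (warned, not
  errored); with heterogeneity enabled this can remove the anomaly region
  from the Arrhenius fit — intended, as those τ are mixture values.
* Event-mode (photon list) correlation, vendor detector formats and
  four-point structure factors are out of scope.
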