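# Methods notes

## Flux calculation

Headspace N₂O mixing ratios (ppbv) convert to mass by the ideal gas law:
moles N₂O = (ppbv·10⁻⁹)·pV/RT, times 28 g N mol⁻¹ (two N atoms per
molecule). The net rate of a bottle is the 0→24 h headspace mass increment
divided by dry soil mass and the enclosure length, assuming linear
accumulation over the enclosure — adequate for 24 h enclosures at these
rates, and exactly invertible (the synthetic generator uses the inverse).
Units are fixed at **ng N₂O-N g⁻¹ dry soil d⁻¹** throughout; flux
literature is often silent on moist-vs-dry basis and per-hour-vs-per-day,
so every CSV header carries the unit string. Headspace volume defaults to
bottle volume (125 ml) minus soil displacement at an assumed bulk density of
1.3 g cm⁻³ (configurable, overridable with a measured volume).

Cumulative emission is the trapezoid rule over the sampled days. The
interval from day 0 to the first measured day has no data; the default
extends the first measured rate backward at constant value, with a
`day0_rule="zero"` alternative (linear ramp from zero) because no
integration convention is universal.

## Partitioning estimator

With net rates under 0 Pa / 10 Pa / 10 kPa C₂H₂,
`consumption = r10k − r10` and `production = r10k − r10 + r0`. The identity
`production − consumption = net` is exact per replicate and per bootstrap
draw and is enforced by tests. Replicate-paired aggregation (compute gross
rates per replicate, then mean ± SE) is the primary mode; a "propagated"
mode derives SEs in quadrature from treatment-level member SEs. Negative
gross estimates are retained and flagged, never truncated (truncation would
bias cell means); only the nitrification-share output also reports a
0-censored value alongside the raw one.

Algebraic note: partial inhibition of nitrification (efficiency η_nit < 1 at
10 Pa, same factor at 10 kPa) cancels out of `r10k − r10 + r0`, so the gross
production estimator is unbiased with respect to η_nit; the bias
−(1−η_nit)·f_nit·P lands entirely on the nitrification-derived production
estimate `r0 − r10`. Partial inhibition of N₂O reduction (η_cons < 1 at
10 kPa) biases the consumption estimate to η_cons·C. Both statements hold
exactly under the generator's rate model and are asserted in tests.

## Bootstrap + Monte-Carlo inference

Because production is consumption plus the shared control rate, their
errors are artificially correlated; naive propagation misstates pairwise
contrasts. Inference therefore resamples replicate triplets with
replacement within each cell (case bootstrap), adds independent Gaussian
noise to each member rate (Monte-Carlo measurement layer), recomputes the
statistic, and reports percentile intervals (B = 1000 default) and
two-sided bootstrap p-values `min(1, 2·min(P(diff≥0), P(diff≤0)))` for
temperature contrasts within fertilization × day. No multiplicity
adjustment by default (per-comparison reporting); Holm is available.

The Monte-Carlo sd default is `"auto"`: the pooled within-cell member-rate
SD divided by √2. A pure case bootstrap at n = 4 replicates is markedly
anti-conservative (measured type-I error ≈ 0.16 at nominal 0.05); the added
noise acts as a smoothed-bootstrap bandwidth and restores calibration
(≈ 0.05–0.07 in 500–1000-repetition null simulations, asserted within a
3-SE binomial band in the acceptance suite). Passing a known measurement
error, or 0 to disable the layer, overrides the default. Degenerate input
(zero variance, mc_sd = 0) yields zero-width intervals and p = 1.

## Q₁₀ estimation

The van't Hoff form R = α·e^{βt} is log-linear, so the default fit is OLS of
ln R on temperature (exact on true exponentials, scale-invariant in Q₁₀);
nonlinear least squares on the raw scale is available for comparison.
Non-positive emissions make the log undefined and raise — no offset is ever
applied silently. Replicate series can be fitted per replicate (default;
mean β reported, per-replicate βs retained for bootstrap comparison) or
pooled. Between-treatment Q₁₀ differences use a replicate bootstrap of the
per-replicate fits, consistent with the partitioning machinery; two-point
fits reduce to the closed form Q₁₀ = (R₂/R₁)^{10/(t₂−t₁)} and are
cross-checked against the regression path.

## Community statistics

T-RF processing: peaks < 50 bp are discarded (boundary closed — 50.0 bp is
kept); binning is single-pass and seeded: scanning ascending fragment
lengths, a bin opens at the smallest unassigned length and collects the
closed-open window [seed, seed+2 bp). This is deterministic and
order-stable; exact re-binning of an already-processed matrix is a no-op
(tested). Bins present in ≤ 2 % of samples (strict inequality to keep) are
dropped; rows are relativized by peak height (not area). An optional
minimum-height noise filter is off by default since no universal threshold
exists.

Bray–Curtis Σ|x−y|/Σ(x+y) is semi-metric (triangle inequality can fail; no
metricity is asserted — the PCoA helper simply drops negative eigenvalues).
The Mantel test correlates lower-triangle vectors and permutes one matrix's
rows/columns jointly, one-sided greater by default (positive association is
the scientific question here); p = (1+count)/(permutations+1). PERMANOVA
partitions ΣΣd²/n into among/within components per term with
pseudo-F = (SS_a/df_a)/(SS_w/df_w) and free label permutation; each factor
is tested as an independent one-way term (sequential partitioning of
crossed terms is not implemented). On univariate Euclidean distances the
pseudo-F equals the classical one-way ANOVA F exactly. scikit-bio is used
in the test suite as an independent cross-check of these statistics, never
as the implementation.

## qPCR

Standard curves are OLS of Cq on log₁₀ copies; efficiency
E = 10^(−1/slope) − 1 (slope −3.3219 ⇔ E = 1). R² ≤ 0.99 warns (the
conventional quality bar). Quantification inverts the curve and scales from
reaction to soil: copies g⁻¹ dry = 10^((Cq−b)/m)·dilution·(elution/template)
/ (extraction mass·(1−moisture)). The elution volume has no kit-independent
default and must be supplied. Technical-replicate CVs are computed on
back-transformed copies, the reporting scale. Cq outside the calibrated
range flags extrapolation; Cq beyond a configurable cutoff (35) is treated
as no-template-like.

## Synthetic generator: what it emulates, and what a green test shows

The generator is phenomenological. True gross production P and the true
consumption ratio ρ = C/P are looked up from per-(fertilization, day,
temperature) calibration tables encoding the qualitative structure the
analysis must resolve: rates decline over the 30-day incubation; CT
consumption rises with temperature early and falls late; NPK production
rises steeply with temperature at days 15/30 while its consumption stays
flat (so net emission in NPK is strongly temperature-sensitive); MNPK rates
peak at 25 °C. Treatment-mean ρ values are CT 0.63, NPK 0.48, MNPK 0.75 —
grand mean 0.62, span 0.48–0.75. Net-rate series between campaign days use
log-linear interpolation of P and linear interpolation of ρ.

Stochastic layers, chosen once: a mean-one lognormal replicate effect
(CV 15 %) shared by a replicate's bottles and multiplying (P, C) jointly;
a mean-one lognormal perturbation of ρ per replicate (CV 15 %,
anaerobic-microsite heterogeneity of the consumption fraction); Gaussian
measurement noise per bottle-observation with sd = max(0.3,
0.10·|rate|) ng N g⁻¹ d⁻¹ (GC error grows with concentration, with an
absolute floor). These levels were set from two calibration anchors — grand
mean estimated ratio ≈ 0.62 and within-regime production–consumption
correlation ≈ 0.98 — and then frozen. With these defaults the estimated CT
correlation sits at ≈ 0.99: the structural spread of the calibrated rate
tables bounds it from below, and pushing noise high enough to hit 0.98
exactly destabilizes the ratio anchor; both anchors are comfortably inside
their stated tolerances as is.

Communities are Dirichlet draws (40 T-RF bins per gene, concentration 50)
around cell-level compositions shifted along fixed effect directions:
fertilization dominates the clade I landscape, sampling time dominates
clade II, temperature is minor for both — so PERMANOVA should (and does)
recover exactly that contrast at n = 4. Abundances are lognormal around
gene-specific fertilization/time/temperature effect tables (clade I dips at
day 15 and recovers; clade II declines monotonically after day 3 and is
insensitive to temperature; both are depressed under NPK). Nutrient
trajectories are cosmetic first-order curves anchored at realistic initial
pools (e.g. NH₄⁺ 13.05 µg g⁻¹ in NPK) and 30-day nitrate build-ups
(68/101/90 µg g⁻¹).

A green pipeline test therefore establishes: the estimators invert the
stated rate model exactly in the noiseless limit, remain calibrated under
the stated noise, and detect the programmed community/abundance structure.
It does **not** establish robustness to features real studies have and the
generator lacks: C₂H₂ diffusion limitation and catalytic artefacts,
non-Gaussian GC error, day-to-day drift within a bottle, T-RF drift between
runs, or qPCR inhibition. The generator also makes no attempt to calibrate
the strength of abundance–rate correlations; they emerge qualitatively
(positive, clade II stronger) but not at any target value.

The null generator zeroes every treatment effect (common P = 8, ρ = 0.5,
one community distribution, one abundance level) for type-I-error
calibration of the bootstrap, Mantel and PERMANOVA machinery.

## Numerical / design choices

- Percentile bootstrap intervals (not studentized): simplest defensible
  construction; the CI-brackets-point property is checked for B ≥ 1000.
- The total bottle census of a real campaign is not hard-coded anywhere;
  arms are enumerated independently (net monitoring, C₂H₂ campaigns,
  destructive sampling), and a flag records whether campaign bottles are
  fresh per day (default) or re-used, which changes the bottle census but
  not the enumerated observation units.
- Day-0 baseline bottles carry no temperature assignment (sacrificed before
  incubators); design types enforce this.
- The nitrate-buildup share 100·(1 − NH₄₀/ΔNO₃) floors at zero; with the
  packaged nutrient anchors it evaluates to ≈ 98 / 87 / 96 % for
  CT / NPK / MNPK.
- Seeds: every stochastic routine takes an explicit seed and is
  reproducible bit-for-bit; the pipeline manifest records all seeds and
  parameters and hashes stably.

## Known limitations

- PERMANOVA tests factors marginally; interaction terms (reported in
  crossed designs elsewhere) are out of scope.
- The C₂H₂ method's mechanistic biases are only *characterized* (via the
  η parameters of the generator), never corrected.
- Mixed-effects modelling, ANOVA/Tukey post-hocs, boosted-tree variable
  importance and NMDS ordination are deliberately not reimplemented; they
  are stock methods available in general statistics packages.
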