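# Methods

This note documents the models implemented in `fspibr`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a user should know before trusting or
extending the results.

## Experimental design

The generator enumerates the layout of a two-species, two-temperature
heat-wave experiment: per species, 4 aquaria are destructively sampled at
day 6 (before the temperature rise, so still at the control temperature)
and 4 aquaria per species × treatment at day 12, plus 4 animal-free
procedural-control aquaria — 28 aquaria in total. Stocking densities are
fixed at 3 native and 4 invasive individuals per aquarium; these densities
are back-derived from the reported per-day sample totals (12/16 at day 6,
24/32 at day 12 over 4 and 8 aquaria respectively) and compensate the
species' body-size difference with near-equal biomass. They are an
assumption of the generator, not a measured quantity, and are exposed as
configuration.

The realised thermal contrast of the conditions is carried as the pooled
post-day-6 water temperatures, 18.12 °C (constant) vs 22.13 °C (heat
wave): a 4.01 °C contrast sustained for six days, which satisfies the
usual marine-heat-wave definition (≥5 consecutive days above the seasonal
90th percentile).

## f-SPI image model and analysis

### Synthetic profile images

One rendered image stands for one aquarium side photographed under UV.
Geometry defaults mirror the study camera: 12 cm internal width per side
(four sides merged to 48 cm) and an 88.9 µm/px scale; most tests and the
default pipeline run use coarser scales (100–400 µm/px) purely as a
problem-size choice — every statistic is scale-covariant and the scale is
a parameter. The scene is three flat colours plus optional noise: a bright
grey-blue water column, dark grey-blue sediment, and orange luminophore
pixels. The tracer colour is a deliberately *dark* orange: luminophores
are sediment grains, so their luminance must fall on the sediment side of
the water/sediment cut or a surface-lying grain would locally displace the
detected interface by one pixel.

Tracer pixels are placed per column at depths drawn below the local
interface from one of four laws: `surface` (depth 0), `uniform(0, d)`,
`exponential(mean)` (truncated at the sediment base — the only law with
unbounded support; the bounded laws raise if they do not fit), and
`point(d)`. The interface itself is flat, stepped, or sinusoidal, with
optional per-column integer jitter; the jittered surface is the ground
truth. Noise, default off, is salt-and-pepper speckle (fraction of pixels
set to pure black/white) plus a per-pixel Gaussian luminance offset; the
"default noise" level used in robustness tests is 1% speckle and σ = 8
8-bit counts.

### Analysis

Segmentation is a deterministic HSV box (hue 0.02–0.13, saturation ≥ 0.35,
value ≥ 0.35, matched to the tracer colour and configurable, since the
original plugin's threshold is unpublished). The interface is, per column,
the topmost pixel darker than a luminance threshold (default 0.42, between
the sediment and water luminances), smoothed by a running median over 11
columns to suppress single-column speckle; columns with no sediment are
flagged, logged and excluded. Depth is measured per column relative to the
local interface — not to a global horizontal line — and pixels detected
above the interface are floored to depth 0, treating them as segmentation
artefacts rather than negative depths. The median over an even pixel count
is the midpoint of the central pair. Aquarium-level roughness is the
arithmetic mean of the four per-side values, while the depth statistics
are computed on the merged four-side image.

On noise-free renders the whole chain (segment → trace → measure) is
exact: it reproduces the metrics computed from the generator's own mask
and surface, pixel for pixel. This is the oracle-equivalence property the
test suite enforces, together with scale covariance, column-permutation
invariance, and monotonicity of `L_max`/`L_mean` under added deep pixels.

## Biomarker model

Raw values for individual k of species i, treatment j, biomarker b are
generated as `baseline[i][b] × multiplier[i,j,b]^(day=12) × ε`, with ε
lognormal, mean 1, CV 0.25 by default — multiplicative noise is the
natural choice for strictly positive assay values with roughly constant
relative error. The default multipliers encode the measured relative
changes of the study conditions (e.g. ×3.06 DNA damage in the native
species; ×0.62 ETS and ×1.65 lipid in the invasive species under the heat
wave); biomarkers reported only at the species level share their
multiplier across treatments, and biomarkers with no detectable change
keep 1.0. Baseline means are plausible assay values in conventional units
(e.g. reserves in mJ/g, ETS in mJ/g/h, giving CEA ≈ 57); they are
arbitrary up to scale because normalization and the index are unit-free,
and they are configuration, not constants.

The per-component reserve changes and the reported CEA change are not
mutually consistent (a mean of ratios is not a ratio of means), so CEA is
never parameterised directly: it is derived per individual as Ea/Ec, and
the generator reports the *implied* CEA multiplier (baseline-share-weighted
reserve multiplier over the ETS multiplier) as the ground truth for
recovery tests. When a target CEA effect is wanted exactly — the ×1.63
invasive heat-wave scenario in the acceptance suite — the three reserve
multipliers are set uniformly, which makes the implied multiplier exact
and independent of baseline shares.

Mean-percent-change estimates carry a first-order delta-method CI that
propagates the sampling variance of both the day-12 mean and the day-6
baseline mean; ignoring the baseline term would understate the interval
noticeably at these sample sizes (n = 12–16 per species-day). Empirical
coverage of the 95% interval is 92–95% over 200 replicates — slight
undercoverage expected from the first-order approximation at small n.

## IBR_v2

The index follows the reference-deviation formulation: per-individual
log-ratio Y against the species' day-6 mean, standardisation to Z within
biomarker × grouping cells using the sample (n−1) SD, a day-6 reference
term Z_D6 taken literally as the mean day-6 log ratio (not
re-standardised), deviation A = Z − Z_D6, and the index as Σ|A| over SOD,
CAT, DNAd, LPO, IDH, LDH and CEA, reported per condition as mean ± SE over
individuals. Logs are base 10 by default; the base is exposed because the
two halves of the computation respond differently to it — Z is invariant
(the base rescales Y, µ and s together) while Z_D6 scales with
1/log(base), a property the tests assert explicitly.

The grouping of µ and s is genuinely ambiguous in the field's usage. The
default computes both within species × treatment, which matches
per-condition index reporting; a pooled per-species ("general mean")
grouping is selectable. The two readings differ in one important way:
under per-condition standardisation every cell's mean Z is zero by
construction, so the *condition-mean* deviation per biomarker collapses to
−Z_D6 and carries no treatment contrast (the index itself, built from
|A|, is unaffected). Star plots therefore use the pooled grouping, where
the sign of the mean deviation tracks genuine induction vs inhibition;
cells with zero variance are guarded (contribution 0, with a warning)
rather than crashing, since degenerate synthetic panels hit them.

## GLS model selection

Responses are modelled as y = Xβ + ε over the species × treatment
factorial with treatment-coded dummies. Heteroscedasticity is handled by
per-stratum variance weights Var(ε) = σ²δ²_g (δ = 1 in the first stratum),
the strata being none, species, treatment, or their crossing. β and σ²
are profiled out analytically; the remaining log-ratios are maximised
numerically (L-BFGS-B on the profiled ML or REML log-likelihood). The REML
criterion includes the −½log|X'V⁻¹X| term with the (n−p) normalisation;
the resulting log-likelihoods, AICs, coefficients and variance ratios
agree with R's `nlme::gls` (ML and REML, with and without `varIdent`
weights) to ~1e-5, which the suite checks by calling R on a shared
fixture. AIC counts fixed coefficients + σ² + free variance ratios, and
likelihood-ratio df is the parameter-count difference of the compared
models.

The workflow is: (1) choose the variance structure by REML AIC on the full
fixed model, ties toward fewer parameters; (2) backward-select fixed terms
by ML likelihood-ratio tests at α = 0.05, interactions always dropped
before their main effects; (3) re-express the final model under REML.
Simulation properties enforced by the acceptance suite: the df = 2 LR test
(dropping treatment with its interaction under a true null) has empirical
size in [0.03, 0.07] over 2000 replicates at n = 80; the generating
variance structure is selected in ≥80% of 100 replicates at n = 200, both
for homoscedastic truth (identity chosen over per-species weights; the
theoretical rate with an AIC penalty of 2 per parameter is ≈84%, which is
why these simulations use the pre-registered two-candidate set
{identity, species} rather than all four structures) and for a 2:1
per-species SD contrast.

Procedural-control aquaria carry no factor levels and are excluded from
all factorial fits.

## Pipeline and reproducibility

`run_all` chains the stages on synthetic inputs and writes a manifest with
a config hash and the SHA-256 of every output. All randomness derives from
one master seed via a seeded generator; rendered PNGs, CSVs and the star
SVG (fixed hash salt, no date metadata) are bit-identical across reruns of
the same config. The default run uses 250 µm/px images and 1500 tracer
pixels per aquarium as its problem size; both are config knobs.

## Limitations

* The image model is flat-colour with simple noise: no sediment texture,
  no illumination gradients, no partial-volume tracer pixels, no burrow
  structures. Passing recovery tests shows the measurement chain is
  correct, not that segmentation thresholds transfer to real photographs —
  on real data the HSV box and luminance threshold must be tuned against
  the QC overlays.
* Biomarker noise is independent across biomarkers within an individual;
  real panels are correlated, so the synthetic IBR dispersion is, if
  anything, optimistic. Absolute index levels depend on the noise model
  and are not comparable to any published value.
* The depth laws are static snapshots; no time-resolved mixing model is
  attempted (the design images once, at the end of the experiment).
* GLS covers fixed effects with variance weights only; aquarium random
  effects are out of scope, so individual-level biomarker fits treat
  individuals within an aquarium as independent.
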