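# fspibr

Analysis pipeline for laboratory heat-wave experiments on benthic bivalves,
where the question is whether a native and an invasive congener (e.g.
*Ruditapes decussatus* vs *R. philippinarum*) respond differently to a
simulated marine heat wave, at two levels of biological organisation:

* **Ecosystem process** — bioturbation, measured by fluorescent
  sediment-profile imaging (f-SPI): orange luminophore tracer particles are
  seeded on the sediment, aquarium sides are photographed under UV, and the
  depths to which animals have mixed the tracer are read off the images.
* **Subcellular state** — a panel of biomarkers (antioxidant enzymes SOD
  and CAT, oxidative damage LPO and DNAd, metabolic enzymes IDH and LDH,
  electron-transport-system activity ETS, and energy reserves), integrated
  into a single stress index per individual.

The package is aimed at experimental ecologists and ecotoxicologists who
need this analysis chain as tested, scriptable code rather than a one-off
spreadsheet, and at methodologists who want a synthetic test bed with known
ground truth for each stage.

## What it computes

**Particle reworking (f-SPI).** The four side photographs of an aquarium
are merged, calibrated (µm/px), and thresholded in HSV space into a binary
luminophore matrix. The sediment–water interface is traced per column; the
burial depth of each tracer pixel is measured below its column's interface.
Outputs per aquarium: `L_mean`, `L_median`, `L_max` (mean / median /
maximum mixed depth, cm) and `SBR` (surface boundary roughness = highest −
lowest interface elevation, cm, averaged over sides).

**Baseline-normalised biomarkers.** Each day-12 biomarker value is
expressed as percent change against the species' day-6 (pre-heat-wave)
mean:

$$B^n_{i,j} = \frac{B^{D12}_{i,j} - \bar{B}^{D6}_i}{\bar{B}^{D6}_i}\times 100$$

The energy budget is appended per individual: available energy
Ea = protein + carbohydrate + lipid, consumption Ec = ETS activity, and the
cellular energy allocation CEA = Ea/Ec.

**IBR_v2 stress index.** Per individual and biomarker,
$Y = \log_{10}(B^{D12}/\bar{B}^{D6})$ is standardised to
$Z = (Y-\mu)/s$ within biomarker × condition; the day-6 reference term is
$Z^{D6} = \overline{\log_{10}(B^{D6}/\bar{B}^{D6})}$; the deviation index
is $A = Z - Z^{D6}$, and

$$\mathrm{IBR}_{v2} = \sum_b |A_b|$$

over the integrated set (SOD, CAT, DNAd, LPO, IDH, LDH, CEA), summarised
per condition as mean ± SE, with star (radar) plots of the per-biomarker
deviations.

**Minimal adequate models.** Each response is modelled against
species × treatment by generalized least squares with optional per-stratum
variance weights: the variance structure is chosen by REML AIC, fixed terms
are pruned by backward selection with ML likelihood-ratio tests
(interactions before main effects), and the final model is re-expressed
under REML. The likelihood surface matches R's `nlme::gls` (verified in the
test suite).

**Synthetic data with ground truth.** Because raw data from such
experiments are rarely released, a seeded generator reproduces the study
design (28 aquaria; 2 species × 2 treatments × 2 sampling days), renders
f-SPI images with pixel-level truth (choice of burial-depth law and
interface shape), and draws biomarker panels with configurable
multiplicative treatment effects under lognormal noise. Every downstream
stage is validated against this truth.

## Worked example

```python
from fspibr import synthetic, fspi, biomarkers, ibr

# render one aquarium side with known truth and analyse it
truth = synthetic.render_fspi_image(
    depth_law=("exponential", 1.2),      # mean burial depth 1.2 cm
    interface_law=("sinusoid", 2.0, 0.3, 8.0),
    n_luminophore_px=5000, seed=11, pixel_scale_um=100.0,
    width_cm=12.0, height_cm=8.0)
mask = fspi.segment_luminophores(truth.image, pixel_scale_um=100.0)
surface = fspi.detect_interface(truth.image)
print(fspi.depth_metrics(mask, surface))

# a full biomarker panel -> energy budget -> IBR_v2
design = synthetic.build_design()
panel = synthetic.sample_biomarkers(design, seed=1)
panel = biomarkers.add_energy_budget(panel)
print(ibr.compute_ibr(panel).summary.round(3).to_string(index=False))
```

prints

```
ReworkingMetrics(L_mean=1.180296311227575, L_median=0.84, L_max=5.69, SBR=0.6)
        species treatment  mean    sd  n    se
   R_decussatus        CT 5.577 1.539 12 0.444
   R_decussatus        HW 5.551 1.810 12 0.522
R_philippinarum        CT 5.607 1.079 16 0.270
R_philippinarum        HW 5.589 1.428 16 0.357
```

The recovered `L_mean` of 1.18 cm sits close to the generating exponential
mean of 1.2 cm (truncated at the sediment base); the index summary gives
the per-condition stress level, mean ± SE over individuals.

The same chain is available from the shell:

```sh
heatwave-pipeline init-config --out cfg.yaml
heatwave-pipeline run --config cfg.yaml --outdir results/
heatwave-pipeline fspi-analyze --images a.png b.png c.png d.png \
    --width-cm 12 --out metrics.csv
heatwave-pipeline normalize --in panel.csv --out normalized.csv
heatwave-pipeline ibr --in panel.csv --out ibr.csv --starplot stars.svg
heatwave-pipeline gls --in responses.csv --response L_mean --out report.json
```

`run` executes the whole synthetic pipeline and writes a manifest with the
SHA-256 of every output; identical config + seed give bit-identical runs.

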