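# sporetrack

Quantitative analysis of programmed peptidoglycan (PG) degradation during
bacterial sporulation, built around three measurements used to study the
rod-to-sphere transition of *Myxococcus xanthus*:

1. **Single-particle tracking PALM (sptPALM)** of PG-degrading enzymes
   (lytic transglycosylases tagged with PAmCherry): sub-pixel spot
   localization by symmetric 2D Gaussian fitting, frame-to-frame linking,
   classification of each trajectory as *immobile* (PG-bound) or *mobile*
   (freely diffusing), and diffusion-coefficient estimation from the mean
   squared displacement, with bootstrap uncertainties.
2. **Cell morphometry**: segmentation of cells/spores in 2D images and the
   length/width aspect ratio L/W, which falls from ≫ 1 (vegetative rods)
   to ≈ 1 (spherical spores) as sporulation proceeds.
3. **Muropeptide quantification**: UPLC chromatogram baseline subtraction,
   peak integration, relative abundances, anhydro-muropeptide fractions
   (the signature products of lytic transglycosylases) and cross-sample
   total-PG comparison.

A first-class synthetic-data module generates ground-truthed trajectories,
camera movies, cell images and chromatograms, so the entire pipeline is
testable without any raw microscopy or chromatography data.

## The model

A tracked enzyme particle is either bound to the (effectively stationary)
PG sacculus or diffusing freely in the membrane/periplasm. A trajectory is
classified **immobile** when the area it explores over its classification
window — the first 0.4–1.2 s of the track — stays within one camera pixel
(160 nm × 160 nm), i.e. both bounding-box spans are < 160 nm. Tracks that
mix bound and free segments exceed the one-pixel box and count as mobile.

For mobile particles the diffusion coefficient *D* follows from the
time-averaged mean squared displacement with the free-diffusion law

    MSD(Δt) = 4 D Δt,

fitted through the origin on the first four lags (Δt = 0.1–0.4 s at
10 Hz). Population statistics report the immobile percentage and the mean
per-track *D* of the mobile subpopulation; uncertainties are standard
deviations over 1,000 bootstrap resamples of the tracks.

## Worked example

Simulate a mixed enzyme population in its strongly PG-bound state — the
`ltgA-30min` preset: 31.5% immobile, mobile D = 1.80 × 10⁻² μm²/s — and
recover the population statistics:

```python
from sporetrack.pipeline import load_config, run_pipeline

cfg = load_config(overrides={
    "seed": 7, "stages": ["simulate", "analyze"],
    "simulate": {"n_particles": 1200, "preset": "ltgA-30min"},
})
report = run_pipeline(cfg, "demo_run")
print(report["population"])
```

prints

```
{
  "n_total": 1200,
  "n_immobile": 402,
  "n_mobile_with_D": 798,
  "immobile_fraction_pct": 33.5,
  "mean_D_um2_s": 0.018470186538808105,
  "bootstrap_sd_D_um2_s": 0.0003052146582560272,
  "n_bootstrap": 1000,
  "fit_mode": "through_origin"
}
```

The classifier recovers the simulated immobile fraction (33.5% vs the
true 31.5%; the ~2-point excess comes from the few mobile tracks that
happen to stay within one pixel for their whole window) and the MSD fit
recovers the mobile-population D (1.85 vs 1.80 × 10⁻² μm²/s) with a
bootstrap standard deviation of 3 × 10⁻⁴ μm²/s.

The same stages run from the shell:

```bash
sporetrack simulate --preset ltgA-30min --n-particles 1200 --seed 7 --out sim
sporetrack analyze sim/ground_truth.csv --n-boot 1000 --seed 7
sporetrack run --config run.yaml --seed 7 --out results
```

plus `sporetrack localize / track` for movie inputs, `sporetrack
morphology` for images and `sporetrack muropeptides` for chromatograms.

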