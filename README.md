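# memfrac

Quantification of the plasma-membrane-associated fraction of a fluorescently
tagged protein from three-channel confocal images, with supporting FCS
diffusion-model fitting and ratiometric FRET/intensity utilities.

## Who this is for

Cell biologists and microscopists who co-express a membrane marker (e.g.
Lck-CFP), a cytoplasm marker (soluble RFP) and a YFP-tagged protein of
interest, and want to answer: *what fraction of my protein's signal sits on
the plasma membrane?* — including fractions far too small to see by eye.

## The method

Intensity profiles are scanned perpendicular to the membrane (10 px wide
lines, bilinear interpolation), aligned on the membrane-marker peak,
oriented cytoplasm-left, normalized to the cytoplasmic plateau, and unmixed
by non-negative least squares on x ∈ [−2.25, 2.25] µm:

    f_YFP(x) = a_CP · f_RFP(x) + a_PM · (f_CFP − f_RFP)(x),   a_CP, a_PM ≥ 0

where f_CFP − f_RFP is the pure-membrane basis (the membrane marker carries
a cytoplasmic pool that must be subtracted). The headline readout is the
peak of the membrane component, `pm_peak_percent = max(a_PM·f_corr)·100`,
in percent of the cytoplasmic level, with a 95% CI from a line-level
bootstrap (n = 1000, CI = estimate ± 1.96 × bootstrap SD).

A built-in synthetic-cell generator (disk cell, excluded nucleus, membrane
as a thin circular line source, per-channel Gaussian PSFs, Poisson noise)
provides exact ground truth, `expected_pm_peak = 100·m/(√(2π)·σ·c)`, so
every pipeline stage is testable without external data. The FCS module fits
autocorrelation curves with a triplet + two-component 3-D diffusion model,
globally linking diffusion times across measurements, and converts times to
coefficients via a calibration sample (D = D_ref·τ_ref/τ_D). See
`docs/methods.md` for the full model description and numerical choices.

## Worked example

```bash
# render a synthetic cell (membrane marker at 300%, protein of interest at
# 20% of cytoplasm) plus 20 radial line ROIs and the ground truth record
memfrac simulate --out cell.tif --rois rois.zip --truth truth.json --seed 3

# run the full unmixing pipeline
memfrac unmix --stack cell.tif --rois rois.zip --out results/ --seed 0
```

which prints:

```
a_CP=1.0030 a_PM=0.0665 pm_peak=18.70% [18.27, 19.13]
```

Read: the protein's profile decomposes into a cytoplasmic component at
~1.0× the cytoplasm marker and a membrane component peaking at 18.7% of the
cytoplasmic level (95% CI from the bootstrap). The ground truth for this
simulation is 20%; the ~6% shortfall is the known multiplicative sampling
transfer of bilinear line scans at 140 nm pixels (see `docs/methods.md`) —
identical for all constructs imaged with the same settings, so comparisons
between constructs are unaffected. `results/summary.json` and
`results/components.csv` hold the coefficients and the CP/PM component
profiles with CI bands.

The same library drives FCS fitting (`memfrac fcs-fit`), FRET ratio traces
(`memfrac fret`), nuclear/cytoplasm ratios (`memfrac nucratio`), fold-change
over untransfected controls (`memfrac foldchange`) and notched boxplot
statistics (`memfrac boxstats`), all importable from Python as
`memfrac.profiles`, `memfrac.fcs`, `memfrac.ratiometrics`, etc.

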