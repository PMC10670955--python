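# uroquant

Quantification pipeline for ex vivo studies of the urothelial blood–urine
barrier in mouse bladder. It packages, as tested reusable code, the four
bespoke measurements such studies rely on:

- **Nuclear density (hyperplasia)** — from two-channel fluorescence
  micrographs (urothelium marker + nuclear stain): segment the epithelial
  band, segment and watershed-split its nuclei, filter objects by area
  (`A_min`, `A_max = factor × A_med`), measure the band's centerline length
  from its medial axis, and report `ρ = N / L` in nuclei/µm — plus a
  sensitivity analysis of the density over the full threshold grid and a
  comparison of automated against manual counts.
- **TEER** — Ussing-chamber readings to absolute transepithelial electrical
  resistance, `TEER = (R_total − R_blank) × A_window` (Ω·cm², Ohm's law on
  raw ΔV/ΔI pairs), normalized to the 30 min equilibration anchor, with
  exact two-tailed Mann–Whitney comparisons per time point (full
  enumeration at small n: complete separation gives p = 2/C(n₁+n₂, n₁),
  e.g. 0.0286 at 4 vs 4).
- **ROI fluorescence** — mean intensity and fold change vs. a negative
  control; summed gray value normalized to 10,000 µm² of region area.
- **Assay statistics** — qPCR `−ΔCt` vs. an endogenous control, urinary
  K⁺/creatinine (mmol/g), Shapiro–Wilk-routed t vs. Mann–Whitney testing,
  and `p_adj < 0.05` deregulated-gene set logic with shared/unique counts
  across contrasts.

A synthetic-data module (`uroquant.phantom`) generates calibrated tissue
phantoms with exact ground truth, Ussing traces, and assay tables, so the
whole pipeline is testable without microscope or animal data. See
`docs/methods.md` for the algorithms, defaults and limitations.

## Worked example

```python
from uroquant import phantom, density, teer

# a calibrated phantom: curved band, known centerline length, exact density
params = phantom.TissuePhantomParams(
    centerline_kind="arc", arc_radius_um=50.0,
    image_height_px=320, image_width_px=320,
    gaussian_noise_sd=20.0, debris_count=5, clutter_count=5, seed=1,
)
micro, truth = phantom.generate_tissue_phantom(params)
result = density.run_density_pipeline(micro)
print(f"density {result.density_per_um:.4f}/um, truth {truth.true_density_per_um:.4f}")
print(f"band length {result.band_length_um:.1f} um, truth {truth.centerline_length_um:.1f}")

# TEER: noiseless traces round-trip the generator baseline exactly
trace = phantom.generate_ussing_trace_set(
    phantom.UssingSimParams(noise_cv=0.0, pll_drop_fraction=0.6), 1)[0]
series = teer.process_trace(trace)
print(f"anchor {series.anchor_teer_ohm_cm2:.1f} Ohm*cm2, "
      f"relative at 45 min {series.value_at(45, relative=True):.1f}%")
```

prints

```
density 0.1214/um, truth 0.1210
band length 156.5 um, truth 157.1
anchor 150.0 Ohm*cm2, relative at 45 min 40.0%
```

The phantom's arc has analytic centerline length π·50 ≈ 157.1 µm; the
pipeline recovers it and the planted nuclear density to well under 1%
despite noise, sub-µm² debris and out-of-band clutter. The TEER trace drops
to 40% of its equilibration anchor at 45 min because the simulated
polycation exposure removes 60% of the baseline resistance.

A CLI mirrors the library: `uroquant simulate`, `uroquant density
run|sensitivity|validate-manual`, `uroquant teer process|compare`,
`uroquant fluoro quantify`, `uroquant stats qpcr|urine|compare|dge-filter`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic inputs from the given seed, runs the full
pipeline end-to-end — density with sensitivity analysis on all three
centerline geometries, TEER processing with per-time-point exact tests,
and the assay statistics — prints what it computed, and writes the JSON
result object to `--out`.
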