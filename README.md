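# mitoquant

Quantification pipeline for the image- and curve-based assays used to
characterise mitotic chromosome-movement phenotypes in cultured cells —
the kind of phenotypes produced by chromokinesin (e.g. KIF22) perturbations:
altered polar ejection forces, failed or reversed anaphase segregation
(recongression), lobed interphase nuclei, changed protein turnover on
chromatin, and reduced proliferation.

It is written for microscopists and image analysts who have time-lapse or
fixed-cell fluorescence data plus simple ROI annotations (pole and marker
coordinates), and who want the measurements behind the figures as tested,
scriptable functions rather than one-off macros. Because raw imaging data
for such studies are rarely redistributable, the package ships a synthetic
microscopy generator (`mitoquant.synthetic`) that produces ground-truth
labelled inputs for every assay, so the whole measurement chain is
verifiable end to end.

## The measurements

* **Polar ejection forces** (`mitoquant.pef`). In a monopolar spindle the
  chromosomes form a ring around the single pole. Within a 12.5 μm circular
  ROI centred on the pole, the radial profile of DNA-stain intensity is
  computed (mean intensity per 1-px annulus, pixel-centre binning) and the
  distance from the pole to the profile maximum is reported: stronger
  ejection forces push the chromatin ring farther out.

* **Anaphase segregation** (`mitoquant.anaphase`). Intensity is sampled
  along the line through both spindle poles, split at the midpoint into two
  half-spindles, and the global maximum of each half locates its chromosome
  mass. The distance between maxima, tracked per frame, gives the
  separation-vs-time series d(t); recongression appears as a rise–dip–rise.
  The same split applied to a centromere channel, together with the pole
  coordinates, decomposes motion into chromosome-to-pole (anaphase A) and
  pole-to-pole (anaphase B) parts. Mass broadness is the full width at half
  maximum, FWHM = 2√(2 ln 2)·σ, of a Gaussian fitted to each half-profile.

* **Nuclear morphology** (`mitoquant.nuclei`). Solidity = area / convex-hull
  area per segmented nucleus; the 5th percentile of the control population
  sets the threshold below which a nucleus is called abnormal. Thresholds
  are dataset-relative and carried with their provenance.

* **FRAP** (`mitoquant.frap`). Background-subtracted bleached-ROI intensity
  normalized to the first frame imaged; summaries are the immediately
  post-bleach percentage and the recovery percentage at a chosen time
  (default 220 s).

* **Proliferation** (`mitoquant.growth`). Well counts normalized to t = 0,
  wells kept only if the first-frame count is in [10 000, 20 000], doubling
  time τ by least squares of log₂(count) on time over 0–48 h, and the
  closed-form predictions N(T) = b^(T/τ) with b = 2 − f for a non-dividing
  fraction f. With τ = 20.72 h the 48-h predictions are 4.98 (b = 2),
  3.42 (b = 1.7, 30 % non-dividing) and 2.18 (b = 1.4, 60 % non-dividing).

## Worked example

Simulate five noisy monopolar cells with the chromatin ring at 3.7 μm, then
measure them:

```bash
mitoquant simulate monopolar --ring-radius-um 3.7 --n-cells 5 --noise-sd 100 --out sim_pef
mitoquant pef --images 'sim_pef/*.tif' --poles sim_pef/truth.csv --out out_pef
```

`out_pef/pef.csv`:

```
cell_id,distance_to_max_um,n_bins,status
cell000,3.6500000000000004,125,ok
cell001,3.75,125,ok
cell002,3.75,125,ok
cell003,3.75,125,ok
cell004,3.75,125,ok
```

Each row is one cell's pole-to-DNA-maximum distance; all five recover the
true 3.7 μm ring radius to within one 0.1 μm annulus despite 10 % peak
noise. The growth assay works the same way:

```bash
mitoquant simulate growth --n-wells 2 --noise-cv 0.05 --out sim_g
mitoquant growth --counts sim_g/counts.csv --out out_g
```

`out_g/growth_predictions.csv` holds the closed-form 48-h expectations
(4.98 / 3.42 / 2.18 for 0 / 30 / 60 % non-dividing cells), and
`growth_summary.csv` the per-well doubling-time fits — 21.8 h and 20.9 h
here, scattered around the true 20.72 h by the 5 % count noise. Every run
directory also contains a `manifest.yaml` recording the package version,
the full configuration and its hash, and a checksum of every input.

The library mirrors the CLI one-to-one; see the module docstrings in
`src/mitoquant/` for the Python API.

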