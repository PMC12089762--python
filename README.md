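# lakebloom

Detection, phenology, trend and driver analysis of lake algal blooms from
daily multi-band reflectance scenes — with a fully synthetic data generator
so the whole pipeline is testable against known ground truth.

## What it does

- **synthetic** — generates lakes (geometry, water-presence rasters, ice
  seasons, hemispheres), daily five-band scenes (443/555/645/859/1240 nm)
  with known bloom patches, cloud censoring, daily meteorology and annual
  nutrient series, all reproducible from one seed.
- **detection** — classifies each valid lake pixel as bloom via nFAI
  thresholding (NIR excess over the red–SWIR linear baseline, brightness
  normalized), CIE chromaticity green-region screening, and historical
  water-presence exclusion of vegetation fringes.
- **metrics** — cloud-weighted daily bloom frequency
  `(A_Bloom/A_valid)·(A_valid/A_Lake)²`, 15-day running mean over observed
  days, and per-bloom-year onset / persistence / annual frequency with ice
  and hemisphere handling (July–June windows for non-frozen southern lakes).
- **trends** — eligibility filtering (blooms in ≥ half of observed years),
  per-lake OLS slopes with four-way significance classes, global median
  series with relative growth rate (%/yr), and a matched-pair comparison of
  period growth rates.
- **drivers** — Pearson correlation of daily frequency with temperature /
  precipitation / wind and of annual frequency with fertilizer N/P and ten
  anthropogenic-N input categories (plus subset sums); per-lake best-factor
  attribution and temperature-threshold bloom statistics.

## CLI

```sh
lakebloom run --config config.yaml --out out/          # end-to-end
lakebloom simulate --config config.yaml --out sim/     # scenes + series
lakebloom detect --scenes sim/scenes --geometry sim/geometry --out det/
lakebloom metrics --detections det/ --geometry sim/geometry --out annual.csv
lakebloom trends --metrics annual.csv --out trends/
lakebloom drivers --detections det/ --met sim/met --nutrients sim/nutrients \
    --metrics annual.csv --out drivers/
```

See `examples/config.yaml` for the configuration schema. Exit codes:
0 success, 2 config error, 3 data-format error, 4 stage failure.

Scene stacks are NetCDF files with dimensions `day × band × y × x`, a band
coordinate in nm and a byte validity mask; all tables are CSV with ISO-8601
dates; the pipeline report is JSON with floats at 6 significant digits
(byte-identical across runs with the same seed).

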