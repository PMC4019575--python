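# benthomap

Benthic habitat mapping from multibeam echosounder (MBES) data. The package
integrates three MBES data sources — backscatter **angular response**, the
normalized **backscatter mosaic**, and **bathymetry** — into a single
random-forest classification workflow with importance-driven feature
selection, plus a fully synthetic survey generator so the whole pipeline is
testable end to end without any external data.

## Pipeline

1. **synthetic** — generate bathymetry, a habitat class map, per-beam
   backscatter samples with class-specific angular response (optionally with
   per-sample noise and along-track gain drift), and labelled ground-truth
   points with a 70/30 train/test split.
2. **mosaic** — statistically compensate the angular dependence of the
   samples (sliding window of 25 pings, reference angle 30°), grid the
   normalized levels to a dB mosaic, and quantise to 8 bit.
3. **segmentation** — region-growing segmentation of the mosaic (similarity
   threshold with a geometric ramp, minimum-area merging) and vectorisation
   to polygons (GeoJSON).
4. **angular** — compile one mean angular-response curve per segment from the
   *pre-normalization* samples and extract four features over 30–50°
   incidence: mean, least-squares slope, skewness, kurtosis; rasterise them.
5. **derivatives** — six bathymetry derivatives (slope, aspect, rugosity,
   maximum curvature, BPI, complexity) and six mosaic derivatives (HSI
   red/green/blue, GLCM homogeneity/entropy/correlation).
6. **model** — random forest (ntree = 200, m = ⌊√p⌋), scaled variable
   importance, two-rule incremental feature selection (≤3 variables at a
   time, importance gaps < 0.2), full-map prediction.
7. **evaluate** — error matrix, overall accuracy, Kappa with delta-method
   variance, pairwise Z tests (critical value 1.96), per-class accuracies,
   and the all-pairs R² layer-correlation table.

## CLI

Each stage is a subcommand of the `benthomap` entry point:

```sh
benthomap simulate --seed 1 --noise-sd 2 --out-dir survey/
benthomap mosaic survey/samples.csv survey/bathymetry.tif --window 25 --ref-angle 30 --out-dir survey/
benthomap segment survey/mosaic_8bit.tif --similarity 20 --min-area 150 --out-dir survey/
benthomap arfeat survey/samples.csv survey/segments.tif --angle-range 30 50 --out-dir survey/
benthomap derive survey/bathymetry.tif survey/mosaic.tif survey/mosaic_8bit.tif --out-dir survey/
benthomap train survey/ground_truth.csv survey/*.tif --ntree 200 --seed 1 --subset auto
benthomap predict survey/ground_truth.csv survey/*.tif --out habitat_map.tif
benthomap evaluate runs.json survey/*.tif --out-dir reports/
```

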