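# seagrass

Shallow-water benthic habitat mapping and interannual change detection from
multiband (blue/green/red) water-surface reflectance rasters.

The pipeline implements:

1. **Radiometry & water column** (`seagrass.optics`) — conversion of
   at-surface reflectance `R` to remote-sensing reflectance `Rrs = t·R/Q`,
   the analytical shallow-water model
   `R = R∞ + (Rb − R∞)·exp(−2·Kd·Z)` forward and inverted (water-column
   correction), deep-water reflectance estimation from a polygon, and
   optically-deep masking (default limit 16.5 m).
2. **Satellite-derived bathymetry** (`seagrass.bathymetry`) — second-order
   polynomial of depth against the blue/green log-ratio
   `x = ln(Rrs(475)/Rrs(555))`, calibrated from in-situ points, applied per
   pixel, smoothed with a 5×5 low-pass filter and validated against held-out
   points (r², RMSE).
3. **Classification** (`seagrass.classification`) — random forest
   (100 trees, 2 features per split, Gini) on the corrected
   bottom-reflectance bands, trained from 50 points per class.
4. **Accuracy assessment** (`seagrass.accuracy`) — error matrices (rows =
   predicted, columns = reference) with overall, producer, user and kappa
   statistics.
5. **Change detection** (`seagrass.change`) — per-class areas in hectares,
   percent change (earlier epoch as baseline), OLS area-vs-year trend
   slopes, and per-pixel gain / no-change / loss maps.
6. **Synthetic scenes** (`seagrass.synthetic`) — a forward-model scene
   generator (depth gradient, depth-structured four-class habitat map,
   class bottom spectra, sensor noise, train/validation/depth point sets)
   so the whole pipeline is testable without any imagery.

Rasters are plain TIFFs with the grid geometry and band/stage/class
metadata stored as JSON in the TIFF description tag; points are CSV,
polygons GeoJSON/WKT, configuration YAML.

## CLI

```sh
seagrass simulate --config spec.yaml --out scene/ --seed 42
seagrass depth fit --surface scene/surface.tif --points scene/depth_points.csv --out model.yaml
seagrass depth predict --surface scene/surface.tif --model model.yaml --out sdb.tif
seagrass depth validate --depth sdb.tif --points val_depth.csv
seagrass correct --surface scene/surface.tif --depth sdb.tif --mask-limit 16.5 --out rb.tif
seagrass classify train --scene rb.tif --points scene/train_points.csv --seed 42 --out clf.joblib
seagrass classify predict --scene rb.tif --model clf.joblib --out habitat.tif
seagrass assess --map habitat.tif --points scene/val_points.csv --out report.json
seagrass change --maps m2011.tif --maps m2016.tif --years 2011 --years 2016 --out change/
seagrass run --config pipeline.yaml          # full multi-epoch pipeline
```

`seagrass run` reads a YAML config listing per-epoch surface rasters and
train/validation point files, an optics block (per-band `Kd`, `R∞`, `t`,
`Q`), a bathymetry source (depth points to fit, a ready raster, or
polynomial coefficients), the reference epoch used for the single shared
bathymetry, and random-forest settings. It writes habitat maps, accuracy
reports, area series, trend estimates, change maps and a manifest with
parameters and product checksums.

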