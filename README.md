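# nodule4d

Spatiotemporal analysis of osteoblast morphology and collagen-matrix
production in two-channel 3D+time two-photon image stacks, together with a
ground-truthed synthetic scene generator that makes every stage of the
pipeline verifiable offline.

The pipeline quantifies, from a `T x Z x C x Y x X` stack (channel 0 a cell
fluorescence channel, channel 1 a second-harmonic-generation collagen
channel):

* **matrix formation** — SHG isosurface volume/area over time, lacuna voids
  (regional-minima extraction), binarized SHG/EGFP projection-area ratios;
* **cell morphology** — per-cell volume, surface area, Wadell sphericity,
  oblateness/prolateness from second-moment semi-axes, and the
  high-sphericity classification (ψ ≥ 0.7, inclusive);
* **spatial organisation** — IN/ON vs OUT compartment classification
  (concave footprint polygon + lowest-surface-height rule), Delaunay
  triangle-area crowding, and 4 x 4-subROI correlation of high-sphericity
  cell counts with local matrix increase (Spearman, banded strength
  categories);
* **dynamics** — membrane-bleb detection/tracking by temporal-minimum
  subtraction (durations, maximum areas), 4D bleb spots by frame
  differencing with per-plane polarity histograms, and cell motility by
  nearest-centroid tracking;
* **statistics** — one-way ANOVA + Tukey HSD, paired/two-sample t-tests,
  Spearman with a Kolmogorov–Smirnov normality pre-check.

The `synthgen` module renders the three scenarios the analysis expects —
a multi-day nodule time course, a seconds-scale bleb movie (2D or
volumetric), and a treated-vs-vehicle drug-response experiment — as
anti-aliased ellipsoid scenes with a complete `GroundTruth` record of every
rendered object and event. Identical config + seed reproduces stacks
bit-for-bit.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (bleb
duration/area recovery, sphericity-population recovery, subROI partition,
classifier boundary, and the property/oracle suite), one test per
criterion.

## CLI

```sh
nodule4d simulate --scenario nodule --seed 1 --out out/    # render a scene + truth
nodule4d preprocess out/nodule.tif --out filtered.tif --median-radius 1
nodule4d segment out/nodule.tif --out seg/ --timepoint 0
nodule4d morpho out/nodule.tif --out cells.csv --sphericity-threshold 0.7
nodule4d blebs out/bleb.tif --out blebs.csv
nodule4d run --scenario nodule --seed 1 --out report/      # full pipeline
```

`nodule4d simulate` accepts a YAML `SceneConfig` (`--config`); every run
writes the full configuration next to its outputs for provenance.

## Conventions

* Canonical axis order `TZCYX`; loaders normalise other on-disk orders.
* Physical coordinates are voxel index × voxel size, in micrometres;
  `z = 0` is the dish bottom and z increases away from the substrate.
* Time units are declared in the calibration (`s`, `h`, `day`) — never
  inferred.
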