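# airsom

Unsupervised profiling and source apportionment of multisite hourly
air-quality panels. The pipeline extracts recurrent pollutant profiles with
a batch self-organizing map (SOM), classifies the codebook into "air types"
with Ward hierarchical clustering validated by the Davies–Bouldin index,
flags outlier hours through per-sample quantization errors, and disentangles
emission sources by running uncertainty-weighted positive matrix
factorization (PMF) with bootstrap validation on the codebook instead of the
raw data.

Panels carry five pollutants in fixed order — benzene (Ben), toluene (Tol),
PM10, NO, NO2 — one row per (site, hour). A seeded synthetic generator with
planted sources, air-type regimes and extreme PM10 episodes makes every
stage testable end to end without external data.

## Command-line pipeline

```sh
airsom simulate   --seed 42 --out raw.csv --truth truth.json
airsom preprocess --input raw.csv --max-na 1 --out clean.csv --scaling scaling.txt
airsom som        --input clean.csv --map auto --epochs 100 --seed 42 --out model/
airsom cluster    --model model/ --kmin 2 --kmax 10 --out clusters/
airsom pmf        --codebook model/ --factors 4:6 --nboot 100 --seed 42 --out pmf/
airsom report     --model model/ --clusters clusters/ --panel clean.csv --out report/
```

* `preprocess` keeps only timestamps complete at every site (rows with up to
  `--max-na` missing cells survive) and fills residual gaps by iterative PCA
  imputation.
* `som` autoscales the panel and trains the batch SOM; `--map auto` sizes the
  hexagonal grid with the 5·√N heuristic and the data's covariance
  eigenvalue ratio. The model directory holds `codebook.csv`, `meta.json`
  and `scaling.txt`.
* `cluster` cuts the Ward tree at the Davies–Bouldin optimum over the given
  range and exports labels, centroids (scaled and concentration units), the
  score table and Kruskal–Wallis / pairwise Wilcoxon–Bonferroni tests.
* `pmf` back-transforms the codebook to concentration units, builds the
  uncertainty matrix (relative uncertainties per pollutant plus floors),
  scans the factor range with bootstrap validation and exports G, F, species
  fingerprints and diagnostics.
* `report` projects node clusters and quantization-error outliers back onto
  sites and calendar days (`daily_clusters.csv`, `outliers.csv`); an
  optional `--period MM-DD:MM-DD` restricts to a month-day window.

The same functionality is available as a Python API
(`airsom.simulate_panel`, `airsom.train_batch_som`, `airsom.select_k`,
`airsom.fit_pmf`, ...).

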