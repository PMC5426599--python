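# geoprev

Multi-scale geographic analysis of disease period prevalence on planar
polygon geographies:

- **Sex-interaction point-pattern tests** — uncorrected Ripley's K, Cross-L
  and Difference-K with random-labeling simulation envelopes and the
  Diggle-Cressie-Loosmore-Ford (DCLF) integrated-deviation test.
- **Period prevalence** (cases per 10,000 over a study period) per spatial
  unit, pooled exactly across nested aggregation levels.
- **Spatial weights** — first-order Queen contiguity with explicit ferry-link
  augmentation, and k-nearest-neighbor adjacency; row standardization,
  isolate and connectivity diagnostics.
- **Moran's I** — global, local (LISA) and bivariate cross-scale variants
  with full/conditional permutation inference and HH/LL/HL/LH cluster
  classification (deliberately uncorrected for multiple testing).
- **Stratified spatial heterogeneity** — the geographical-detector
  q-statistic with a permutation test.
- **MAUP sensitivity** — random Voronoi re-zonations of the districts with
  per-zonation global Moran tests and per-scheme/union significance
  fractions.
- **Synthetic regions** — Voronoi districts nested in contiguous zones,
  log-normal population allocation with exact totals, proportional or
  clustered sex-marked case patterns, and an island mode that exercises the
  ferry-link path — so the entire pipeline is testable with no external data.

Coordinates are planar meters throughout (UTM-like); there is no CRS
handling. Layers are GeoJSON, cases and edge lists are CSV.

## CLI

Generate a full synthetic input set (layers + cases + ferry links + run
config):

```sh
geoprev fixture --out data/ --preset paper_scale --seed 1
# or with explicit knobs:
geoprev synth --districts 312 --zones 10 --population 3163546 \
              --cases 511 --male-frac 0.467 --seed 1 --out data/
```

Run the full pipeline (sex-dependency → prevalence → weights →
global/local/bivariate Moran → q-statistic → MAUP) from the generated
config:

```sh
geoprev run --config data/config.yaml
```

Outputs land under the config's `out_dir`: per-stage CSVs, GeoJSON cluster
maps, `report.json` and `report.md`. Individual stages are also available
as subcommands (`geoprev sexdep`, `weights`, `moran`, `qstat`, `maup`); see
`geoprev <cmd> --help`.

## Notes

- No edge correction is applied in the K-family estimators; inference is
  always against simulations conditioned on the same window and counts, so
  the boundary bias cancels. Against the theoretical CSR curve the
  uncorrected estimator is biased low at large r.
- Permutation pseudo-p values use `(1 + exceedances) / (1 + n_sim)` and are
  never zero.
- Zero-population units have undefined prevalence and are excluded (with a
  warning) from autocorrelation analyses, never set to zero.
- With a fixed seed every stage is bit-reproducible; the pipeline report is
  byte-identical across reruns of the same config.
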