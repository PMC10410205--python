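# sealspacing

Fine-scale spatial analysis of pinniped haul-out colonies from
georeferenced polygon annotations — one polygon per animal, grouped into
haul-out sites, in a projected metric CRS.

Colonial animals "stay close, but not too close": aggregation is shaped by
predation, thermoregulation and competition, while very small
inter-individual gaps carry pathogen-transmission costs. `sealspacing`
quantifies both sides of this trade-off for hauled-out seal colonies (grey
seal *Halichoerus grypus*, harbour seal *Phoca vitulina*) surveyed in
high-resolution aerial imagery, and is aimed at ecologists working with
annotated survey imagery of colonial species.

## What it computes

For each site, and pooled per species:

- **Nearest-neighbour distances (NND).** For animal *i* with outline
  polygon *P_i*, `NND_i = min_{j≠i} d(P_i, P_j)` where *d* is the minimum
  edge-to-edge Euclidean distance (0 for touching/overlapping bodies).
  Species are compared by quantile regression,
  `Q_q(NND) = β₀ + β₁·1[species]`, at q = 0.5 and 0.25.
- **Neighbourhood density.** Counts of neighbouring centre points within
  1, 3, 5 and 10 m of each focal animal's centroid, compared between
  species with a negative-binomial GLM (log link, ML dispersion).
- **Social distancing.** A spatial-perturbation null: each animal is
  displaced by an isotropic Gaussian whose scale σ is a cross-validated
  kernel bandwidth (averaged per species across sites), keeping its
  orientation; overlapping bodies are separated by 1° rotation steps,
  then 10 cm translation steps in a random direction. This preserves the
  colony's coarse density while erasing fine-scale spacing. A binomial
  GLM then compares the proportion of NNDs < 25 cm between the observed
  and shuffled configurations: a deficit in the observed data is
  short-range avoidance.

A synthetic-colony generator (clustered body-ellipse patterns with a
controllable hard-core gap) stands in for survey data in development and
testing. See `docs/methods.md` for the models, assumptions and design
choices.

## Worked example

```python
import sealspacing as ss

sites = ss.generate_paired_study(sites_per_species=(1, 2), n_grey=120,
                                 n_harbour=80, seed=42)
records = []
for site in sites:
    records.extend(ss.nearest_neighbour_distances(site))

for s in ss.summarize_nnd(records, group_by="species"):
    print(f"{s.group:8s} n={s.n:4d} median NND = {s.median:.2f} m "
          f"(IQR {s.q25:.2f}-{s.q75:.2f})")

test = ss.median_difference_test(records)
print(f"median difference (harbour - grey) = {test.estimate:.2f} m, "
      f"t = {test.statistic:.1f}, p = {test.p_value:.2g}")

grey = sites[0]
observed = ss.nearest_neighbour_distances(grey)
result = ss.shuffle_site(grey, ss.ShuffleConfig(seed=1, bandwidth_override=2.0))
prox = ss.proximity_proportion_test(observed, result.nnd_records)
print(f"grey-like site: observed {100*prox.metadata['observed_proportion']:.0f}% "
      f"vs shuffled {100*prox.metadata['shuffled_proportion']:.0f}% of NNDs < 25 cm, "
      f"z = {prox.statistic:.1f}, p = {prox.p_value:.2g}")
```

Output:

```
grey     n= 120 median NND = 0.43 m (IQR 0.21-0.82)
harbour  n= 160 median NND = 1.02 m (IQR 0.70-1.85)
median difference (harbour - grey) = 0.58 m, t = 6.9, p = 2.8e-11
grey-like site: observed 32% vs shuffled 61% of NNDs < 25 cm, z = 4.5, p = 8.1e-06
```

The grey-like colonies are built denser and with a smaller hard-core gap
than the harbour-like ones, so their median NND is smaller; the quantile
regression recovers that difference with its uncertainty. On the single
grey-like site, shuffling nearly doubles the share of sub-25 cm gaps
(32% → 61%): the generated animals sit further apart at short range than
their coarse density predicts — the planted avoidance signal, recovered.

## Command line

```sh
sealspacing simulate --seed 3 --out colony.geojson   # synthetic study
sealspacing validate colony.geojson                  # input contract check
sealspacing run --config config.yaml --seed 42 --out results/
```

`run` executes the full pipeline (NND → density → shuffle → tests) and
writes CSV tables (`nnd_records.csv`, `nnd_summary.csv`,
`density_summary.csv`, `tests.csv`, 0.25 m-binned observed-vs-shuffled
histograms), shuffled configurations as GeoJSON, a JSON resolution report
and a provenance copy of the configuration; re-running from that copy with
the same seed reproduces every table byte for byte. A minimal
`config.yaml`:

```yaml
input_path: colony.geojson
out_dir: results
radii: [1, 3, 5, 10]
shuffle:
  seed: 42
```

Annotation input is GeoJSON (polygon features with `site` and `species`
attributes) carrying a projected metric CRS such as EPSG:28992; geographic
(degree-unit) coordinates are rejected.

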