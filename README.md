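# citrec

Analytics for citizen-science biodiversity records.

Opportunistic wildlife recording — the kind collated by local records
centres and online portals — is biased in *when*, *where* and *what*
volunteers record. Those biases are usually treated as noise to correct
for; read the other way, they describe volunteer behaviour. `citrec`
turns an occurrence-record table (recorder, date, OSGB grid reference,
species) into that behavioural description, for scheme organisers and
biodiversity informaticians:

- **Engagement profiling.** Per-volunteer metrics — observation count,
  activity ratio AR = active days / linked days, relative activity
  duration RAD = active days / study window, and variation in
  periodicity VP = own mean gap between active days / cohort mean gap —
  are min-max normalised and clustered (Ward WSS-elbow to choose k,
  best-of-restarts k-means to partition, average silhouette width ≥ 0.51
  to validate), yielding dabbler / steady / enthusiast profiles.
- **Spatial recording statistics.** Records at ≤ 1 km precision are
  aggregated to British National Grid monads: records, volunteers,
  informal taxonomic groups and productivity (records/volunteer) per
  cell; Spearman correlations between datasets and metrics; top-10
  hotspot rankings. OSGB references are parsed at any precision,
  including DINTY tetrads.
- **Taxonomic composition and coverage.** Percentages of records per
  higher/informal taxonomic group; recorders, records/recorder and
  British-list species coverage per group.
- **Trait screens.** Records-per-species modelled on species traits
  with quasipoisson GLMs (log link, Pearson-χ²/df dispersion) and
  F-tests, with Bonferroni-adjusted interpretation reported alongside.
- **Synthetic data.** A generator that emulates the assumed structure —
  a three-archetype engagement mixture, hotspot-concentrated effort,
  abundance- and identifiability-driven recording rates, messy grid
  references and recorder-name synonyms — so the whole pipeline is
  testable without proprietary data.

See `docs/methods.md` for the statistical detail and design choices.

## Worked example

```python
from citrec import synthetic
from citrec.records_io import clean_records, IngestPolicy
from citrec.engagement import engagement_table
from citrec.profiling import EngagementProfiler

# 600 volunteers, ~35k records, 5% at coarse (10 km) precision
vols, daily, raw, species = synthetic.simulate_dataset(
    n_volunteers=600, seed=17, coarse_fraction=0.05
)

clean, audit = clean_records(raw, IngestPolicy())
print(audit.to_dict())
# {'n_input': 34917, 'n_rejected_date': 0, 'n_rejected_precision': 1713,
#  'n_rejected_anonymous': 0, 'n_rejected_group': 0, 'n_output': 33204}

individual = clean[~clean["is_group"] & ~clean["is_anonymous"]]
metrics = engagement_table(individual)
results = EngagementProfiler(metrics).fit(seed=17)
print(results.k, round(results.asw, 3), results.accepted)
# 3 0.659 True
print(results.summary().round(3))
```

```
            n_observations  activity_ratio  relative_activity_duration  variation_in_periodicity  n_volunteers  percent_volunteers
profile
dabbler             34.115           0.577                       0.029                     0.927           407                  68
steady              49.651           0.482                       0.046                     1.107           186                  31
enthusiast        1440.571           0.223                       0.223                     2.411             7                   1
```

The 1713 rejected rows are the coarse-precision records (5% of 35k,
unusable at monad resolution). The elbow of the Ward WSS curve selects
k = 3 and the silhouette width 0.659 validates the partition
(threshold 0.51). The summary rows are raw-unit cluster centroids: most
volunteers are dabblers (few observations, short linked periods), a
third are steady, and a handful of enthusiasts contribute observations
at two orders of magnitude above the rest — recovering the mixture the
generator planted.

The same stages run from the shell:

```sh
citrec simulate --out raw.csv --n-volunteers 600 --seed 17 --mapping-out mapping.csv
citrec ingest --in raw.csv --out clean.csv --audit audit.json
citrec engagement --in clean.csv --out engagement.csv
citrec profile --in engagement.csv --out profiles/ --seed 17
citrec spatial --in clean.csv --out cells.csv --geojson cells.geojson
citrec taxa --in clean.csv --mapping mapping.csv --out taxa/
citrec run --config run.yaml   # everything from one YAML
```

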