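# sturseq

State-sequence analysis of long-term acoustic-telemetry detections, built
for classifying migratory behavior in lake-dwelling, river-spawning fishes
such as lake sturgeon (*Acipenser fulvescens*) in the Laurentian Great
Lakes. It is aimed at movement ecologists who have multi-year receiver
detection histories and want reproducible, rule-based behavioral
classifications instead of purely visual ones.

## What it computes

Starting from detection events (fish, timestamp, receiver) and a receiver
classification table (receiver → habitat, region), the package:

1. **Filters** detections and fish: min-lag false-detection removal
   (a detection is dropped when its nearest same-fish, same-receiver
   neighbor is more than *tf* = 3600 s away), tag-life truncation (10 y),
   maturity (< 1 m total length removed), detection-history span (≥ 2 y),
   spawning evidence (≥ 1 April–June detection at/near a spawning river),
   and analysis-timeframe coverage.
2. **Builds daily location histories** at habitat (river / lake /
   Lake St. Clair) and regional (e.g. LM, MR) resolution with
   last-observation-carried-forward imputation. On multi-location days the
   first detection sets the day's state while carry-forward starts from
   the last. Days before the first detection are *missing*; days after the
   final detection are *void*.
3. **Computes optimal-matching edit distances** between sequences under a
   geographic substitution-cost matrix — cost 0 for the same state, 1 for
   adjacent habitats/regions, 2 for non-adjacent; constant indel cost 1;
   missing-vs-observed cost 2 (which pins sequences to calendar time) —
   normalized by the longer sequence length:
   `d(x, y) = OM(x, y) / max(|x|, |y|)`.
4. **Clusters** the dissimilarity matrix with Ward's agglomerative method
   (Lance–Williams recurrence on squared dissimilarities) and selects the
   starting number of behavioral groups by average silhouette width
   (smallest k with ASW ≥ 0.5, else the k maximizing ASW, kmax = 10).
5. **Classifies** each fish into one of seven migratory behaviors with a
   deterministic rule cascade over its river episodes — river resident,
   annual interlake, annual winter river, annual summer river,
   intermittent two-step, and annual/intermittent spring-river migrants,
   the last split by the periodicity ratio (observed years per spring
   trip; ≤ 1.5 → annual, > 1.5 → intermittent) — plus lake-residency
   fraction and residency class.
6. **Summarizes**: contingent route signatures ("LSC→DR→LE"),
   behavior × population frequency tables with whole-percent shares,
   lake-residency means ± SD, and chi-square goodness-of-fit tests of
   sex ratios within behaviors.

Because raw telemetry of this kind is rarely public, the package ships a
synthetic-data generator (`sturseq.synthetic`) that emulates detection
histories for all seven behavioral archetypes with configurable detection
probability, transition-date jitter, and migration periodicity — every
downstream stage is tested against its known ground truth.

## Worked example

```python
import pandas as pd
import sturseq as ss

cfg = ss.SimulationConfig(n_fish_per_archetype=2, years=4, seed=7)
stations = ss.default_network()
detections, metadata, truth = ss.simulate_cohort(cfg, stations=stations)
stations_df = pd.DataFrame(
    [{"receiver_id": s.receiver_id, "habitat": s.habitat, "region": s.region}
     for s in stations]
)
frame = (cfg.start_date, cfg.end_date)
events, fish, reports = ss.apply_filter_cascade(detections, metadata, stations_df, frame)
hab = ss.build_daily_sequences(events, stations_df, frame, "habitat")
reg = ss.build_daily_sequences(events, stations_df, frame, "region")
for fid in ["annual_spring_river_00", "intermittent_two_step_00", "river_resident_00"]:
    a = ss.classify_behavior(hab[fid], reg[fid])
    print(fid, a.behavior, round(a.lake_residency, 3), a.residency_class, a.periodicity_ratio)
```

prints

```
annual_spring_river_00 annual_spring_river 0.94 lake_dominant 1.0
intermittent_two_step_00 intermittent_two_step 0.646 lake_dominant None
river_resident_00 river_resident 0.0 river_dominant None
```

i.e. the spring-river migrant spends 94% of observed days in the lake and
entered the river every observed year (periodicity ratio 1.0 → annual),
the biennial two-step migrant is lake-dominant at 64.6%, and the river
resident never leaves its river. The generator's label is recovered for
every fish in this noise-free cohort.

The same pipeline is available from the shell:

```bash
sturseq simulate --seed 7 --n-fish 2 --years 4 --out run_inputs/
sturseq run-all --config config.yaml --out run/
```

where `config.yaml` points at the detections/stations/metadata CSVs;
`run/` then contains filter reports, wide-format sequence CSVs, the
dissimilarity matrix, the ASW group selection, per-fish assignments, and
the contingent/frequency/residency tables.

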