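# reeftrack

Analysis tools for **passive acoustic telemetry** of reef fish: given the
detection logs of an array of moored acoustic receivers, classify tagged
fish into behavioral groups, quantify their residency and movements
between habitat patches of an artificial seascape, and test their diel
(day/night) activity patterns — with the environmental variability of
acoustic detection removed by fixed sentinel transmitters.

The package grew out of the analysis of white seabream (*Diplodus
sargus*) monitored for months around an artificial-reef (AR) system and
the nearest natural rocky reef (NR), plus harbor seawalls (SW) and a
distant rocky coast (CV). It is aimed at movement ecologists working
with coded-transmitter receiver arrays (e.g. VEMCO VR2W exports).

## What it computes

**Quality control.** Single daily detections (a tag heard once on a
calendar day, pooled across receivers) are removed as probable
code-collision false positives. Fish released during a high-risk window
with a detection period under 20 days and heard only at their release
receiver are excluded as presumed tagging mortalities.

**Sentinel correction.** Fixed control tags pinging every 9 min probe
the detection probability *p* of each reef per hour-of-day *h* and ISO
week *w*. Fish counts are rescaled by the normalized corrective
coefficient

```
c(w, h) = p̄(w) / max(p(w, h), p_floor)
```

so that uniform detectability is a no-op and corrected counts stay on
the raw scale. Counts are area-standardized to detections · km⁻²
(sampling areas 1.69 km² AR, 0.75 km² NR).

**Residency and classification.** Per fish: detection period DP (days,
first to last detection, inclusive), detection rate DR (% of DP days
with a detection), residency index RI (per-habitat % share of the
detection record) and EOPH (excursions outside the preferred habitat:
maximal runs of hourly bins detected only away from it). The rule

* DR < 50 % → transient (T),
* else RI ≥ 70 % on a reef → AR- or NR-resident,
* else → no preferred habitat (NPH)

assigns the behavioral group; connectivity summaries count the fish
linking each habitat pair.

**Diel analysis.** Sunrise/sunset from the NOAA solar-position
algorithm delimit day and night. Hourly detection counts per
(transmitter, day, hour) are modeled with a Poisson GLMM,

```
log μ = β₀ + β₁·day + β₂·size + β₃·day×size + u_day + v_transmitter
```

with crossed random intercepts and a Laplace-approximated likelihood
(implemented in-package; validated against `lme4::glmer` and the plain
GLM limit). Pearson correlation of fish vs sentinel hourly profiles and
a one-way ANOVA of size across groups guard against environmental and
sampling artifacts.

**Wavelet periodicity.** Morlet (ω₀ = 6) continuous wavelet transform
of hourly chronograms on dyadic scales (2–256 h, 8 voices/octave), with
pointwise 95 % significance against a chi-square AR(1) red-noise null
and the cone of influence, to detect 24-h periodicity.

**Synthetic data.** A seeded generator emulates the whole study: fish
occupying habitats by per-archetype Markov chains (nocturnal
AR-residents, diurnal NR-residents, NPH switchers, transients),
ping-interval jitter (45–95 s fish, ~9 min sentinels, 151-day battery)
and an environmental detectability curve with dawn/dusk dips — so every
stage can be tested against known truth.

## Worked example

The package ships the published 74-fish summary table as a reference
dataset:

```python
from reeftrack import StudyConfig, load_table2, classify_table, connectivity_summary

cfg = StudyConfig()
table = load_table2()
labels = classify_table(table, cfg)
print(labels.value_counts().to_dict())

conn = connectivity_summary(table)
print(conn["visited_fish_per_habitat"])
print(conn["residents_without_excursions"], "of", conn["n_residents"])
```

prints

```
{'NR': 33, 'AR': 20, 'T': 15, 'NPH': 6}
{'NR': 61, 'AR': 55, 'SW': 7, 'CV': 17}
21 of 53
```

i.e. 33 natural-reef residents, 20 artificial-reef residents, 15
transients and 6 fish without a preferred habitat; 61 fish touched the
natural reef at least once, 55 the artificial reefs, 7 the seawalls and
17 the distant coast; and 21 of the 53 residents never left their
preferred habitat.

A full synthetic study runs end to end from the command line:

```sh
reeftrack simulate --seed 1 --out study/
reeftrack qc study/detections.csv --stations study/stations.csv \
    --tags study/tags.csv --out study/clean.csv --report study/qc.json
reeftrack residency study/clean.csv --stations study/stations.csv \
    --tags study/tags.csv --out study/summary.csv
reeftrack diel study/clean.csv --stations study/stations.csv \
    --tags study/tags.csv --habitat AR --out study/glmm_ar.csv
```

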