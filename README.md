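# perivasc

Quantification of perivascular drug penetration in tumor tissue from
multichannel fluorescence microscopy, with Weidner hotspot microvessel
density (MVD) counting, arm-comparison statistics, and a fully seeded
synthetic-field simulator for validation.

## The scientific problem

Intraarterially delivered chemotherapy (e.g. doxorubicin in transcatheter
therapy of liver cancer) concentrates around tumor microvessels and decays
with distance from them. A standard way to quantify this is to image the
drug's auto-fluorescence together with a CD31 immunostain of the vessels on
the same section and measure, for every drug-positive spot, the distance to
the nearest vessel. `perivasc` implements that measurement as a tested,
reusable pipeline:

1. **Vessel binarization** — any non-zero pixel of the pre-masked CD31
   channel is vessel (Otsu or fixed thresholds for raw channels).
2. **Distance map** — the Euclidean distance transform *D(p)* assigns every
   pixel the distance (µm) to the nearest vessel pixel.
3. **Spot detection** — drug-positive pixels are grouped into 8-connected
   components; each spot is reduced to its center point.
4. **Penetration distance** — per spot, *d* = *D*(center); per field, the
   mean over spots; per animal, the mean over three high-fluorescence
   fields (×100, 1.09 mm²) selected by a sliding-window scan that skips
   necrosis/artifact exclusion masks.
5. **MVD** — the vessel mask is scanned at low magnification (×40,
   6.82 mm²) for vascular hotspots; microvessels (single endothelial cells
   or contiguous clusters = connected components) are counted in three
   disjoint ×200 (0.27 mm²) windows and averaged (Weidner method).
6. **Statistics** — cells are reported as mean ± SD (*n*−1); the two
   sacrifice-time subgroups pool into exact "Total" rows via

   s²_pooled = [ (n−1)(s₁² + s₂²) + n((m₁−m)² + (m₂−m)²) ] / (2n−1),

   and arms are compared with one-way ANOVA followed by Fisher's LSD-t
   using the within-group mean square.

Because real stained sections are rarely available with ground truth, the
package ships a forward simulator: edge-enriched vessel point processes,
spots seeded from perfused vessels at distances drawn from an exponential
(or half-normal) law with arm-specific scale λ, intensity decaying as
I₀·e^(−d/τ), unperfused vessels, avascular patches, necrotic exclusion
regions, and Gaussian background — with every spot's exact distance to the
nearest vessel surface recorded as ground truth.

## Worked example

```python
from perivasc import (RunConfig, SyntheticFieldSpec, generate_field,
                      field_penetration, SummaryStats, combine_subgroups,
                      anova_oneway, lsd_t)
from perivasc.synthetic_data import calibrated_drug_threshold

# one 1.09 mm^2 field, exponential decay law with lambda = 40 um
spec = SyntheticFieldSpec(spot_rate=1500, decay_scale_lambda_um=40.0, seed=42)
image, truth = generate_field(spec)
cfg = RunConfig(drug_method="fixed",
                drug_fixed_threshold=calibrated_drug_threshold(spec))
m = field_penetration(image, cfg)
print(m.spot_count, round(m.mean_penetration_um, 2))
print(round(truth.spots["true_distance_um"].mean(), 2))
```

prints

```
1338 34.64
30.96
```

1338 spot components are detected (a dense 1024×1024 field fuses some of
the ~1500 seeded spots into single components) and the measured mean
penetration, 34.6 µm, sits within ~12 % of the 31.0 µm ground-truth mean —
itself below λ = 40 µm because a spot's *nearest* vessel is often not the
vessel that seeded it. On larger, less crowded fields the estimate falls
within 3 standard errors of the truth (see the acceptance tests).

Pooling two sacrifice-time subgroup summaries into a Total row and
comparing arms:

```python
total = combine_subgroups(SummaryStats(4, 40.54, 7.23),
                          SummaryStats(4, 32.68, 8.73))
print(f"{total.mean:.2f} +/- {total.sd:.2f} (n={total.n})")
# 36.61 +/- 8.53 (n=8)

groups = [SummaryStats(8, 9.75, 4.01), SummaryStats(8, 36.61, 8.53),
          SummaryStats(8, 74.33, 25.01), SummaryStats(8, 59.68, 27.49)]
res = anova_oneway(groups)            # F=17.33, p=1.5e-06
t, p = lsd_t(groups[2], groups[1], res)  # t=3.94, p=0.0005
```

## Command line

```bash
perivasc simulate --out study/ --seed 1          # synthetic 4-arm study
perivasc measure  --manifest study/manifest.csv \
                  --config study/config.yaml --out results/
perivasc summarize --animals results/animals.csv --out results/
```

`measure` writes `fields.csv`, `animals.csv`, `groups.csv` (group ×
time-point × Total summary rows) and `comparisons.csv` (ANOVA + pairwise
LSD-t per metric and time point). Real studies are driven by the same
manifest CSV: one row per section or per pre-selected field, pointing at
grayscale TIFFs per channel with calibration columns.

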