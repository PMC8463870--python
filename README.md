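# evtirf

Analysis pipeline for single-cell extracellular-vesicle (EV) phenotyping by
four-color TIRF microscopy — with a ground-truthed synthetic field generator,
diffraction-limited spot detection, cross-channel colocalization into 15
phenotype populations, and resampling statistics for comparing conditions.

## The problem

EVs secreted by a single trapped cell are captured on an antibody-coated
surface (anti-CD81 or anti-CD63), immunostained against four markers (e.g.
CD63, HSP70, TSG101, and Annexin V against phosphatidylserine), and imaged by
total internal reflection fluorescence microscopy. Each vesicle appears as a
diffraction-limited spot in the channels whose markers it carries, so the
2⁴ − 1 = 15 nonzero marker combinations define 15 phenotype populations.
Questions a user of this package asks:

- Do occupied wells show more signals per image than empty wells, and how do
  per-image count distributions shift with 1, 2, or 3+ cells?
- What is the population composition, and how does the capture antibody or a
  secretion inhibitor (e.g. the neutral sphingomyelinase inhibitor GW4869)
  change it?
- Are the statistics trustworthy on discrete, tied, per-image counts?

For the last point the package implements a two-sample Kolmogorov–Smirnov test
whose p-value comes from a pooled bootstrap null (D is conservative on tied
counts under the classical null),

    D = sup_t |F̂_x(t) − F̂_y(t)|,    p = (1 + #{D* ≥ D}) / (n_b + 1),

a permutation test on the integrated squared difference of common-bandwidth
kernel density estimates, a distance-covariance independence test
(n·V_n², V_n² = n⁻² Σ_ij A_ij B_ij on double-centered distance matrices) with
a bootstrap null, Pearson channel-correlation matrices, χ² composition tests
with small-class pooling, per-population fold changes, and median ratios.

Because raw microscopy data are not bundled, a forward model generates
realistic fields with known ground truth: Poisson EV counts per image,
phenotypes drawn from a 15-class mixture, Gaussian-PSF spots with log-normal
brightness on a noisy camera background, and single-channel false spots
emulating unspecific adsorption in empty wells. Every analysis stage can
therefore be validated against programmed truth.

## Worked example

```python
import numpy as np
import evtirf as ev

# simulate 100 empty-well and 100 single-cell images (package-default rates)
panel = ev.MarkerPanel()                      # CD81 capture; CD63/HSP70/TSG101/ANXA5 stains
cfg = ev.ImagingConfig(field_area_um2=1089.0) # 33 um side, 330 px fields
c0, c1 = ev.default_conditions()[:2]
exp = ev.generate_experiment([(c0, 100), (c1, 100)], panel, cfg, seed=11)

# detect -> colocalize -> count
from evtirf.detect import DETECTION_COLUMNS, concat_nonempty
det = concat_nonempty([ev.detect_stack(exp.images[i], ev.DetectionParams(),
                                       cfg.pixel_size_um, i)
                       for i in exp.metadata.image_id], DETECTION_COLUMNS)
recs = ev.colocalize_all(det, radius_um=0.2, panel=panel)
counts = ev.count_evs(recs, exp.metadata, panel)

x = counts.loc[counts.condition == "1cell", "total"]
y = counts.loc[counts.condition == "0cell", "total"]
res = ev.ks_bootstrap_pvalue(x, y, n_b=2000, seed=1)
mf = ev.median_fold(x, y)
print(f"D_KS = {res.statistic_value:.3f}, p = {res.p_value:.5f}")
print(f"median fold (1 cell vs empty) = {mf.value:.1f}")
print(f"zero-signal fraction, empty wells = {ev.frequency_distribution(y).zero_fraction:.2f}")
```

Output:

```
D_KS = 0.460, p = 0.00050
median fold (1 cell vs empty) = 2.0
zero-signal fraction, empty wells = 0.40
```

Single-cell wells are clearly distinguishable from empty wells (D ≈ 0.46 at
the bootstrap p-value floor), the median signal count is twice the empty-well
median (the programmed rate ratio is 3; medians of small counts are integer
quantized), and ~40% of these 100 empty-well images contain no signals at all
— the background-adsorption regime the simulator is parameterized for.

The same pipeline runs from the shell on YAML configs:

```bash
evtirf run-all --out runs/demo --seed 11      # built-in demo design
evtirf run-all --config my_design.yaml --out runs/exp1
```

producing `images/*.tiff`, `metadata.csv`, `ground_truth.csv`,
`detections.csv`, `ev_records.csv`, `count_table.csv`, `test_results.csv`,
`frequency_summary.csv`, and a run manifest. See `docs/methods.md` for the
forward model, the detector, the colocalization rule, and every default.

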