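# Methods

`evtirf` implements the computational half of a single-cell extracellular-vesicle
(EV) phenotyping assay: EVs secreted by individually trapped cells are captured
on an antibody-functionalized surface, immunostained against four markers, and
imaged by four-color total internal reflection fluorescence microscopy (TIRFM).
The package simulates such image fields with known ground truth, detects
diffraction-limited signals, colocalizes them across channels into single-EV
records with one of 15 phenotypes, and compares conditions with resampling
statistics. This note documents the models, defaults and design choices.

## Forward model of a TIRFM field

A field is a square region of area `field_area_um2` (default 4,356 µm², i.e.
66 µm side; at the default pixel pitch of 0.1 µm this is a 660 × 660 px image).
Because TIRFM excites only fluorophores within the ~200 nm evanescent layer,
every imaged vesicle is surface-bound and in focus: the axial dimension is not
modeled. EVs are far below the diffraction limit, so each one renders as a 2-D
symmetric Gaussian (the PSF) with `psf_sigma_um = 0.15` by default. A true EV
carries a nonzero 4-bit phenotype bitmask (bit *i* = stain marker *i* of the
panel) and produces a spot in every channel whose bit is set; unspecific
background adsorption produces additional single-channel false spots.

Per image, the true-EV count is Poisson(`ev_rate`) and the per-channel false
spot count is Poisson(`background_spot_rate`). Spot peak amplitudes are
log-normal with `sigma_log = 0.35` (brightness heterogeneity) and median
`snr * background_sd` (default SNR 10, camera background 100 ± 10 counts;
Poisson shot noise is available but off by default). Amplitudes are independent
across channels by default, so the null of the Pearson channel-correlation
analysis is exactly simulable; a log-space correlation option
(`channel_rho`) provides the positive control. Spots may overlap; no minimum
separation is enforced.

Defaults of the emulated experiment design (the generator's defaults *are* the
simulated experiment, not free dials):

| condition | `ev_rate` | `background_spot_rate` | total signal rate |
|---|---|---|---|
| 0-cell (empty well) | 0.0 | 0.2 / channel | 0.8 |
| 1-cell | 1.6 | 0.2 | 2.4 |
| 2-cell | 3.2 | 0.2 | 4.0 |
| 3+-cell | 4.8 | 0.2 | 5.6 |

With these rates ~45% of empty-well images contain zero signals, and the total
signal rate of single-cell wells is three times the empty-well rate — the two
qualitative anchors of the occupancy analysis. The default 15-class phenotype
mixture weights classes by marker count (quadruple-positive 0.25, each
triple-positive 0.10, each double 0.04, each single 0.0275) so the
quadruple-positive population is the single largest, as observed for
single-cell-secreted EVs. Composition vectors are indexed in the canonical
population order: marker count descending, then bitmask descending.

Pixel geometry, camera gain, exposure and thresholds are not constrained by
the assay description; `pixel_size_um = 0.1` (typical EMCCD-TIRF sampling) and
the camera defaults above were fixed once and are configurable.

What the simulation does **not** emulate: evanescent-field intensity decay,
chromatic offsets between channels (channels are emitted pre-aligned; a
per-channel affine hook exists in the classification layer but defaults to
identity), photobleaching, stage drift, cell-body autofluorescence, and
clumped or aggregated vesicles. Tests passing on synthetic fields therefore
validate the analysis logic and its statistical calibration, not robustness to
those instrument artifacts.

## Spot detection

Detection is deliberately simple and fully deterministic, with one
interpretable sensitivity knob:

1. scale-normalized Laplacian-of-Gaussian response at `log_sigma_px`
   (default 1.5 px, matched to the PSF);
2. robust background statistics of the response — median and 1.4826 × MAD;
3. local maxima above `mu + k_threshold * sigma` (default k = 5);
4. greedy suppression of maxima closer than `min_separation_px` (brighter
   peak wins; exact ties broken by smaller (row, col), giving a total order);
5. maxima within `3 * log_sigma_px` of the border are discarded (truncated
   PSFs localize unreliably);
6. sub-pixel refinement by an intensity-weighted 3 × 3 centroid on the
   background-subtracted response.

A constant image yields a zero background SD; detection then falls back to an
absolute threshold floor and logs a warning. Increasing `k_threshold` can
never increase the number of detections, and integer-pixel translation of the
image translates all detections (away from borders). At the default settings
the false-detection rate on blank fields is well below one per field, and
recall/precision on 30-spot fields at SNR 10 exceed 0.95 (measured by the
acceptance suite).

## Colocalization and phenotyping

Detections of different channels within `colocalization_radius_um` of each
other are merged into one EV record. The default radius, 0.2 µm (2 px), is
roughly half the PSF FWHM; the matching rule is a package design choice. The
algorithm is greedy agglomeration: all cross-channel detection pairs within
the radius are visited in order of increasing distance (ties by index), and
two clusters merge when their channel sets are disjoint *and* every cross-pair
of members is within the radius (complete linkage). This yields a single code
path that (a) merges a clean co-located spot group into one record, (b) splits
components containing two detections of the same channel by nearest-pair
precedence, and (c) guarantees the record invariant that member detections are
pairwise within the radius even on chain-like configurations. Every detection
ends up in exactly one record; a record's bitmask is the OR of its member
channels, so a zero mask cannot occur and every counted EV falls in exactly
one of the 15 classes. On small three-channel instances the greedy partition
agrees with the exhaustive optimum (fewest groups, then minimal total
within-group distance) in well over 95% of random cases.

Counting preserves zero-signal images: the count table has one row per
metadata image, so empty images contribute to frequency distributions. The
two-cluster composition summary assigns each EV to the CD63⁺ cluster if its
CD63 bit is set, else to the ANXA5⁺ cluster if that bit is set, else excludes
it; CD63-precedence makes the clusters disjoint and the two fractions sum
to 1. Per-population fold changes are ratios of mean per-image counts with a
Haldane–Anscombe pseudocount of 0.5 in numerator and denominator; with class
means well above the pseudocount a programmed 3× rate difference is recovered
within a few percent, while means of order 1 are visibly shrunk toward unity —
the pseudocount is a bias/variance trade, not a neutral guard. The capture
(immobilization) antibody is metadata, never a phenotype bit.

## Statistics

All Monte-Carlo p-values use the add-one estimator
`p = (1 + #{T* ≥ T_obs}) / (n_resamples + 1)`, so `p ∈ [1/(n+1), 1]` and an
"approximately zero" p-value is representable as the floor.

**KS with bootstrap null.** The two-sample D statistic is the supremum ECDF
difference evaluated on the pooled support, which is exact under ties. Because
the classical KS null is conservative for discrete counts, the p-value is
computed by pooling both samples and redrawing |x| and |y| values with
replacement `n_b` times (default 10,000). The pooled-bootstrap null is the
standard two-sample choice; under matched Poisson nulls the empirical type-I
error sits inside the 99% binomial band at α = 0.01 and 0.05.

**Density-equality permutation test.** The statistic is the integrated squared
difference between Gaussian-kernel density estimates of the two samples,
evaluated on a common 256-point grid with one common Silverman bandwidth
computed on the pooled sample (a shared bandwidth keeps the statistic from
reflecting smoothing differences). The null is built by permuting sample
labels, which is exact. A pooled sample with zero spread is degenerate and
returns p = 1 with a warning.

**Distance covariance.** The statistic is `n · V_n²` with
`V_n² = (1/n²) Σ A_ij B_ij` over double-centered pairwise distance matrices —
zero exactly when either argument is constant, invariant under additive
shifts. The scale of the statistic is this package's own convention and is not
comparable across data scales without normalization. The null is generated by
resampling one margin with replacement (breaking the pairing), the bootstrap
analogue of independence; a permutation option exists for sensitivity
analysis.

**Pearson channel matrix.** Computed on complete per-EV 4-channel intensity
rows: detected channels contribute background-subtracted peak intensities;
undetected channels contribute the background-subtracted raw value measured at
the EV's consensus position. This fill-in policy makes the matrix estimable
without dropping EVs, at the cost of pulling correlations slightly toward the
local-noise level. Zero-variance channels yield missing entries.

**χ² homogeneity.** Standard two-sample χ² on the 2 × k class-count table
without continuity correction. Classes are pooled smallest-combined-total
first into one residual bucket until every expected count reaches 5 (the
bucket itself must clear the threshold); at least two classes must remain.

**Multiple testing.** Population-wise comparisons report raw p-values; a
Benjamini–Hochberg column is available but off by default.

## Reproducibility and problem sizes

A single global seed drives every stage. Per-stage, per-image substreams are
derived by seeding a `SeedSequence` with `(seed, crc32(stage),
crc32(image_id))`, so adding images or stages never perturbs existing streams,
and two runs with the same configuration are byte-identical (images, tables,
p-values; the manifest records wall-clock timestamps and is excluded from that
guarantee). CSVs are UTF-8 with '.' decimals; images are multi-page 16-bit
TIFFs, one page per channel in panel order.

The test and acceptance suites use scaled problem sizes chosen to estimate
each quantity with comfortable margin: 500 repetitions with 199 resamples for
type-I calibration (the add-one estimator makes α = 0.05 and 0.01 exactly
attainable on a 200-point p-grid), 50 full-size fields × 30 spots for detector
quality, 200 images for composition and fold-change recovery, 448
images/condition for the occupancy median-ratio design (the reproduction
script pools ten such replicates — 4,480 images/condition — because the
empty-well zero probability of 0.449 sits near 0.5 and the integer median of a
single replicate is unstable), and a 4-condition × 50-image demo for
end-to-end determinism. These sizes are the package's own benchmark design.

## Known limitations

- Detector equivalence with any specific laboratory's analysis code is not
  claimed; the LoG detector is a transparent stand-alone design.
- The greedy colocalizer is order-deterministic but not globally optimal on
  pathological dense configurations.
- At empty-well signal densities the median is a coarse (integer) statistic;
  ratios of medians on counts are quantized accordingly.
- The distance-covariance statistic's absolute scale depends on the data
  units; only its resampling p-value is scale-free.
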