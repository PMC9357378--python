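# Methods

This note documents the models, algorithms and numerical choices behind
each pipeline stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Image model and conventions

All spatial arrays are `(z, y, x)` ordered, 0-based, with a 2D field stored
as a single z plane. Calibration is carried per axis in µm (`voxel_size`),
and every physical measurement is reported in µm-derived units. Default
connectivity is face connectivity (4-neighbour in 2D, 6 in 3D) — the most
conservative choice against chaining isolated noise voxels — and is
configurable. Objects "intersect the border" when any voxel lies on the
first/last y or x index; z faces are excluded because a 3D slab is still a
2D field of view in depth.

Denoising defaults to Gaussian smoothing with a configurable sigma (a
median filter is available); the kernel is normalized, so total intensity
of interior-supported signal is preserved to well under 1%. Thresholding
is either `fixed` (an explicit, control-calibrated intensity) or `otsu`.
The Otsu variant is an exact exhaustive sweep over the sorted intensities
maximizing the between-class variance w0·w1·(µ0−µ1)²; histogram-binned
implementations can misassign boundary pixels when a mode tail abuts the
inter-mode gap, and the exact sweep removes that artifact at O(n log n)
cost. Whatever the method, the threshold actually applied is returned with
the label map and written to every run log, because a reproducible
analysis must not hide per-slide tuning.

## Rosette lumens

The chain is max-projection of the ZO-1 channel → denoise (σ = 1 px) →
threshold → label → filter. A ring binary's lumen is its filled interior
(hole fill minus the ring): the enclosed apical lumen is the biological
quantity. Filters: border exclusion, minimum lumen area (default 50 µm²),
circularity 4πA/P² ≥ 0.4 and solidity ≥ 0.8 (defaults chosen to pass
planted annuli and reject elongated debris; both configurable).

One numerical subtlety: measuring the lumen as the hole of the thresholded
binary inherits a bias of roughly one pixel of boundary erosion whenever
the threshold sits below the ring's half-maximum (Otsu typically does,
because the blur skirt is included in the foreground class). For a lumen
of radius 6–12 px that is a 5–15% area error. The lumen boundary is
therefore redrawn at the ring's intensity half-maximum: the amplitude is
estimated from the raw projection (the 75th percentile over the ring mask;
denoising flattens a narrow band's peak and would bias the contour
inward), and the contour is traced on the denoised image where noise is
bounded. With this refinement the mean absolute lumen-area error on
seeded fields is about 1%.

Per-group lumen areas then pass through ROUT (Q = 1% by default) with
flagged values retained but marked excluded. ROUT is applied per group,
not pooled, so that genuine group differences are not masked; per-batch
pooling before or after flagging is left to the caller's grouping.

## Mitochondrial morphometry

Segmentation is 3D thresholding + connected components. Restriction to a
marker-positive region keeps objects whose overlap with the region mask is
at least `min_overlap_fraction` (default 0.5) of their volume; survivors
keep their full voxel membership, because clipping would corrupt
morphometrics of boundary-straddling objects.

Skeletonization resamples each object to isotropic voxels at the finest
pitch (nearest-neighbour) before 3D thinning. Thinning operates in voxel
space; on anisotropic grids a flattened object's centerline zig-zags
between planes, inflating geodesic lengths by tens of percent and
occasionally corrupting branch topology. After thinning, skeleton voxels
are classified by 26-neighbour count (endpoint ≤ 1, slab = 2, junction
≥ 3); adjacent junction voxels merge into one junction node, and slab runs
become edges with geodesic lengths summed over physical step lengths.

Metrics:

- **volume** — voxel count × voxel volume (exact by construction);
- **surface area** — marching-cubes mesh at the 0.5 level of the lightly
  smoothed (σ = 0.8 voxel) binary, which converges to analytic areas;
  voxel-face counting is provided as an alternative but overestimates
  curved surfaces ~1.5×;
- **equivalent diameter** — (6V/π)^⅓, the standard analytic definition;
- **sphericity** — Wadell's π^⅓(6V)^⅔/A; discretization can push it a few
  percent above 1 for near-spheres (tolerance 0.03 in the tests);
- **major axis** — the longest endpoint-to-endpoint geodesic through the
  skeleton plus the local object radius (distance-transform value) at each
  terminal, undoing the ~one-radius end erosion of thinning; a digitized
  5 µm cylinder of radius 0.3 µm is recovered within 2%;
- **branches / junctions** — edge count and degree-≥3 node count after
  pruning leaf spurs strictly shorter than a cutoff. The default cutoff is
  adaptive: twice the object's largest local radius. Thinning artifacts
  scale with tube thickness, while an arm that does not extend beyond its
  own junction's diameter is not resolvable in principle; a fixed-length
  cutoff cannot separate the two regimes across object sizes.

## Marker quantification

Nuclear markers: DAPI nuclei and marker spots are detected by threshold +
size gate; a marker spot counts only when its centroid falls inside a
nucleus (an any-voxel mode exists, but the centroid rule is robust to
halo bleed). Several spots in one nucleus count it once, so
`n_marker_positive ≤ n_dapi` holds structurally. The default spot
threshold is `median + 4·(1.4826·MAD)` of the smoothed image — unlike
Otsu, this background-anchored rule stays calibrated when bright spots
occupy a vanishing pixel fraction. Cytoplasmic markers use the ROI mean
intensity. Normalization divides the per-field ratio (count/count or
intensity/intensity) by the pooled control-group mean ratio, making the
control mean exactly 1 and the whole readout invariant to global
intensity rescaling; per-batch control means are a caller-side grouping
choice.

## Statistics

**ROUT** (constant model): Tukey-biweight location (median start, MAD
scale refreshed per iteration, c = 4.685), RSDR = 68.27th percentile of
absolute residuals × √(n/(n−1)), two-sided t p-values on n−1 df for the
residual t-ratios, tested most-extreme-first against the step-up schedule
α_i = Q·(n−i+1)/n, stopping at the first failure. The schedule is
validated empirically rather than by formula: on clean Gaussian samples
(n = 50) the flagged-point rate is ≈1% at Q = 1%, and two planted 8σ
outliers are both found in >99% of samples. Q = 0 disables flagging.

**ANOVA** is the textbook MS_between/MS_within decomposition (cross-checked
against an independent implementation in the tests). **Dunnett's test**
computes t_i = (x̄_i − x̄_c)/√(MS_w(1/n_i + 1/n_c)) and adjusts by the
null distribution of max_i |T_i|, sampled exactly: independent group-mean
normals sharing the control mean, divided by a common χ²_df/df scale.
This reproduces the Dunnett correlation structure for unbalanced designs
without quadrature tables; 10⁵ draws by default, seeded, with the
Monte-Carlo standard error of each adjusted p reported. Family-wise error
calibrates to 0.05 ± 0.02 over 1000 null simulations, and the k = 1 case
agrees with the pooled t-test to 10⁻³. **Fisher's LSD** uses pooled
MS_within with deliberately unadjusted p-values. **BH-FDR** delegates to
the standard step-up implementation. Two-way ANOVA (additive fixed
effects, no interaction) is provided minimally for completeness.

## Metabolomics

TIC normalization divides each sample by its row total; control
normalization divides each metabolite by its control-group mean.
Dysregulation calling runs a one-way ANOVA per metabolite and applies the
joint gate raw-p < α (0.05) AND table-wide BH q ≤ q (0.01) — the
conjunction is implemented literally, with both thresholds recorded.
Called metabolites are segregated to the mutant lines whose Fisher's LSD
contrast against control is significant at α, with direction from the
sign of the control-relative difference. Enrichment is the upper-tail
hypergeometric test of a hit list against each library set (intersected
with the measured universe), BH-corrected across sets.

## Synthetic generators

All generators draw from a single integer-seeded PCG64 stream; identical
(seed, parameters) give identical fixtures. Noise is Gaussian background
plus Poisson shot noise on the signal, with SNR defined as (mean object
intensity − background mean)/background SD; an infinite SNR switches
noise off for analytic comparisons. Objects are rasterized on oversampled
grids (2–4× per axis) and reduced to pixel coverage to limit aliasing.

- **Rosette fields** (512² px at 1 µm/px by default): non-overlapping
  annuli with lumen radii 6–12 µm and 2.5 µm ring thickness over a field
  of decorative DAPI nuclei, plus deliberately planted border-touching
  and sub-minimum decoys; SNR 6. Ground truth records each lumen's
  analytic and rasterized area and whether the standard filters should
  keep it.
- **Mitochondrial volumes** (40×288×288 voxels at 0.2×0.1×0.1 µm):
  straight tubes and 3-arm stars of radius 0.4 µm (≥2 voxels in every
  axis — the regime in which branch topology is recoverable) and arm
  lengths 2–3 µm, blurred by an anisotropic Gaussian PSF (σ = 0.1 µm),
  SNR 8. Star arms carry alternating out-of-plane tilts bounded away from
  zero: a perfectly planar fat star thins to a plate-like medial surface
  whose skeleton can lack a degree-3 voxel entirely — a genuine thinning
  degeneracy, and not a geometry real radially-extending networks
  exhibit. The SOX2 channel is a smoothed-noise blob mask covering a set
  volume fraction.
- **Marker fields**: non-overlapping DAPI nuclei (radius 4 µm), a planted
  fraction carrying coincident 1.5 µm marker spots, plus background spots
  away from any nucleus as bait for the DAPI gate.
- **Grouped measurements**: Gaussian groups with planted ±kσ outliers at
  recorded row indices.
- **Metabolite tables**: log-normal baselines (σ_log = 1 around 100),
  per-sample log-uniform TIC scales (0.5–2), biological noise at CV 10%,
  n = 4 samples/group, and a default effect plan of 8/16/32 affected
  metabolites (nested across the three mutant lines) at 3-fold with
  alternating direction. Peak tables are compositional: TIC normalization
  transfers any change of total signal onto every other metabolite, so —
  as in real profiles, where the TIC is dominated by abundant core
  species — planted metabolites are minor peaks (baseline × 0.1). Without
  this, planting a third of the signal mass at 3-fold makes every
  unaffected metabolite significantly "dysregulated" after normalization,
  which is a property of closed data, not a calling error.

What the generators do not emulate: optical aberrations beyond a Gaussian
PSF, uneven illumination, touching/overlapping rosettes, mitochondrial
networks denser than the planted separation, cell segmentation, missing
values or batch drift in metabolite tables. Passing tests therefore
demonstrate correctness of the measurement chain under the stated image
formation model, not robustness to every artifact of real acquisitions.

## Problem sizes

The test suite and the acceptance script use: 26-object rosette fields;
digitized solids of ~10³–10⁴ voxels; 10 volumes × 4–6 tube objects for
branch recovery; 1000 samples of n = 50 for ROUT calibration; 10,000
ANOVA and 1000 Dunnett null simulations (2×10⁴ MC draws each); 50
effect-bearing plus 100 null metabolite tables (100 metabolites,
4 groups × 4 samples). These sizes give Monte-Carlo standard errors
comfortably below the tolerances being checked while keeping a full run
in the tens of seconds on one CPU.

## Known limitations

- Branch/junction recovery degrades when arms are shorter than about
  twice the tube diameter or when junction geometry is near-planar at
  coarse z pitch; both are resolution limits of thinning, flagged above.
- Dunnett p-values carry Monte-Carlo noise (reported per comparison);
  at 10⁵ draws the standard error near p = 0.05 is ≈7×10⁻⁴.
- The ROUT variant implements the constant-location case only (no
  regression covariates).
- No aggregation score is computed for mitochondrial "aggregation"
  phenotypes: the notion has no operational definition to implement, and
  guessing one would be worse than omitting it.
- Enrichment is plain over-representation; pathway-topology weighting is
  out of scope.
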