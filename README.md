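# organoidmorph

Quantitative morphometry and statistics for neural-organoid microscopy and
metabolomics. The package re-implements, as a tested and scriptable
pipeline, the measurement chain used to characterize patient-derived
neural models of mitochondrial disease:

- **Neural-rosette quantification** — detect, enumerate and measure rosette
  lumens from ZO-1 tight-junction staining: max-intensity projection,
  denoising, thresholding, connected-component labelling, and rejection of
  border-touching, undersized or non-rosette-shaped binaries. The lumen is
  the region enclosed by the ZO-1 ring, reported in µm².
- **3D mitochondrial morphometry** — segment the mitochondrial channel
  (e.g. TOM20) in 3D, optionally restrict to the SOX2⁺ ventricular zone,
  thin each object to a centerline skeleton, and report volume V, surface
  area A, equivalent spherical diameter (6V/π)^⅓, Wadell sphericity
  π^⅓(6V)^⅔/A, skeleton major-axis length, and branch/junction counts.
- **DAPI-gated immunofluorescence quantification** — bright-spot counting
  for nuclear markers (a marker spot counts only when it coincides with a
  DAPI nucleus), ROI mean intensity for cytoplasmic markers, normalized to
  the DAPI denominator and the control group.
- **Robust statistics** — ROUT outlier removal at a target FDR (Q = 1% by
  default): robust location fit, RSDR residual scale (68.27th percentile
  of |residuals| with a √(n/(n−1)) correction), and FDR-scheduled flagging
  of residual t-ratios. One-way ANOVA, Dunnett's many-to-one post-hoc via
  seeded Monte-Carlo multivariate-t integration, Fisher's LSD, and
  Benjamini–Hochberg FDR.
- **Metabolomics** — total-ion-current and control normalization of peak
  area tables, dysregulation calling (ANOVA with a joint raw-p < α and
  BH-q ≤ q gate), per-genotype segregation via Fisher's LSD against
  control, and hypergeometric over-representation analysis against
  GMT-style metabolite-set libraries.
- **Synthetic data** — seeded generators for every stage (ZO-1 ring
  fields, branched 3D tubes under a Gaussian PSF, marker/DAPI fields,
  grouped measurements with planted outliers, log-normal metabolite
  tables with planted fold changes), each returning a ground-truth record
  so the whole pipeline is testable without external data.

## Worked example

```python
from organoidmorph import synthetic_data as syn, rosette_quant as rq, robust_stats as rs

# a seeded ZO-1/DAPI field: 20 valid rosettes plus 3 border-touching
# and 3 sub-minimum decoy rings
stack, truth = syn.gen_rosette_field(seed=1, n_rosettes=20, n_border=3, n_subminimum=3)
report = rq.quantify_rosette_field(stack)
print(f"rosettes detected: {report.n_rosettes}")
print(f"threshold used:    {report.threshold_used:.1f}")

# grouped measurements with one planted 8-sigma outlier: ROUT at Q=1%,
# then one-way ANOVA with Dunnett's post-hoc against control
df, _ = syn.gen_group_measurements(
    group_means={"Control": 100.0, "PDH": 115.0}, n_per_group=20,
    n_outliers=1, outlier_magnitude_sigma=8, seed=1,
)
groups = {}
for g, sub in df.groupby("group"):
    res = rs.rout_clean(sub["value"].to_numpy(), q=0.01)
    print(f"{g}: n={len(sub)}, ROUT flagged {res.n_outliers}")
    groups[g] = res.cleaned
out = rs.dunnett_posthoc(groups, control="Control", seed=17)
print(f"ANOVA F={out.f_statistic:.2f}, p={out.p_anova:.2e}")
for c in out.comparisons:
    print(f"{c.group} vs {c.other}: diff={c.estimate:.2f}, adj p={c.p_adjusted:.5f}")
```

prints

```
rosettes detected: 20
threshold used:    144.7
Control: n=20, ROUT flagged 0
PDH: n=20, ROUT flagged 1
ANOVA F=21.09, p=4.94e-05
PDH vs Control: diff=13.17, adj p=0.00004
```

All 20 planted rosettes are recovered and the six decoys are rejected;
the one planted gross outlier is the one measurement ROUT flags; the
planted 15-unit group shift is detected with a Dunnett-adjusted p-value.

The same stages are available from the shell, e.g.

```sh
organoidmorph simulate rosette --seed 1 --out fixtures/
organoidmorph rosettes --input fixtures/ --out results/
organoidmorph stats --input measurements.csv --control Control --posthoc dunnett --out stats.json
organoidmorph metabo --table metabolites.csv --control Control --library sets.gmt --out metabo/
```

Every run writes a `run_log.json` with all materialized parameters and the
thresholds actually applied, and deterministic stages re-run
byte-identically from their logs.

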