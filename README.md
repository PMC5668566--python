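# polytrans

Translation-state analysis for polysome-profiling studies of neuromuscular
disease models (and any system profiled on sucrose gradients).

Polysome profiling separates a cytoplasmic lysate on a linear sucrose
gradient (e.g. 15%–50%) and records absorbance at 254 nm along the
gradient: free ribonucleoparticles (RNPs) sediment first, then the 40S and
60S ribosomal subunits, the 80S monosome, and finally polysomes — mRNAs
loaded with multiple ribosomes.  `polytrans` turns such traces, and the
companion molecular readouts of a translation study, into quantitative,
tested statistics:

- **FRP — fraction of ribosomes in polysomes.**  With `A_poly` and `A_80S`
  the areas under the polysomal and monosomal parts of the baseline-
  corrected trace,

  ```
  FRP = A_poly / (A_poly + A_80S)
  ```

  Lighter species (RNP, 40S, 60S) carry no assembled ribosome and are
  excluded.  FRP estimates the overall translational engagement of a
  tissue; group comparisons (Student's t), phenotype correlations (Pearson
  and Spearman) and Ward.D/Euclidean clustering of animals on standardized
  (FRP, relative weight, relative righting time) are built in.
- **Co-sedimentation.**  Per-fraction immunoblot intensities of a protein
  (e.g. SMN, RPS6, RPL26) are normalized to per-lane shares; the
  association index sums shares over a target region, and shift statistics
  (Δ index, Δ center of mass in fraction units) quantify redistribution,
  e.g. after EDTA dissociates ribosomes.
- **Translation efficiency.**  From paired polysomal/total expression,
  `log2TE = log2((POL + c) / (TOT + c))` after depth normalization;
  differential TE between groups is assessed by a paired label-permutation
  test on the difference of group means (exact enumeration when feasible)
  with Benjamini–Hochberg FDR.  The qPCR route implements the ΔΔCt method
  with two reference genes (arithmetic mean of reference Cts ≡ geometric
  mean of reference expression) and `log2ΔTE = log2 FC_POL − log2 FC_TOT`.
- **Cell-level effect sizes.**  Percent decrease
  `100 × (1 − mean_case/mean_ctrl)` with t tests for per-cell metabolic-
  labelling (AHA) fluorescence — under both pooled-cells and
  replicate-means units of analysis — and for per-axon ribosome density
  (count/area).
- **Synthetic data with analytic ground truth.**  Every input above can be
  generated with known region areas (closed-form Gaussian integrals), true
  FRP, planted effect sizes and planted log2ΔTE, so estimator accuracy is
  measurable exactly.

## Worked example

`examples/profile_to_frp.py` simulates a noisy trace with known peak areas
and quantifies it:

```
region boundaries (gradient units):
  RNP        [ 0.00,  1.74]  area 0.660 (true 0.677)
  40S        [ 1.74,  2.57]  area 0.157 (true 0.158)
  60S        [ 2.57,  3.35]  area 0.221 (true 0.226)
  80S        [ 3.35,  4.54]  area 0.747 (true 0.752)
  POLYSOMES  [ 4.54, 10.00]  area 1.820 (true 1.852)

FRP estimate: 0.7091   true: 0.7113
```

Boundaries sit at absorbance valleys between assigned peaks; each region's
trapezoidal AUC is close to its closed-form truth, and the FRP estimate is
within 0.003 of the generating value.  The other scripts in `examples/`
cover the cohort/phenotype workflow, co-sedimentation shifts, differential
TE, qPCR ΔΔCt and cell-level effects, each printing what it computes and
what the numbers mean.

A thin CLI mirrors the library for shell use:

```sh
polytrans simulate cohort --seed 1 --out demo/
polytrans frp --profiles demo/profiles --out demo/results
polytrans run --config run.yaml
```

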