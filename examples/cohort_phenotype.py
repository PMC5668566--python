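"""FRP across a synthetic mouse cohort, related to phenotype.

Simulates control and SMA-like groups (lower FRP coupled to lower body
weight and longer righting time), estimates per-mouse FRP from the traces,
tests the group difference, correlates FRP with phenotype, and clusters
mice on standardized (FRP, relative weight, relative righting).
"""

import pandas as pd

from polytrans import (
    cluster_mice,
    compare_frp,
    compute_frp,
    correct_baseline,
    correlate_phenotype,
    integrate_regions,
    relative_phenotype,
    segment_peaks,
    simulate_cohort,
)

profiles, records, truth = simulate_cohort(n_per_group=6, seed=3)

frp = {}
for profile in profiles:
    corrected = correct_baseline(profile)
    areas = integrate_regions(corrected, segment_peaks(corrected))
    frp[profile.metadata["sample"]] = compute_frp(areas).frp

by_geno = {g: [frp[r.mouse_id] for r in records if r.genotype == g]
           for g in ("control", "SMA")}
test = compare_frp(by_geno["control"], by_geno["SMA"])
print(f"FRP control {test.mean_a:.3f} vs SMA {test.mean_b:.3f}: "
      f"t={test.t:.2f}, p={test.p:.2g} (two-tailed)")

for var, get in (("weight", lambda r: r.weight),
                 ("righting time", lambda r: r.righting_time)):
    c = correlate_phenotype(frp, {r.mouse_id: get(r) for r in records})
    print(f"FRP vs {var}: Pearson r={c.pearson_r:+.3f} (p={c.pearson_p:.2g}), "
          f"Spearman rho={c.spearman_rho:+.3f}")

records = relative_phenotype(records)
table = pd.DataFrame({r.mouse_id: {"frp": frp[r.mouse_id],
                                   "relative_weight": r.relative_weight,
                                   "relative_righting": r.relative_righting}
                      for r in records}).T
clusters = cluster_mice(table, k=2)
print("\n2-cluster cut (Ward.D on standardized variables):")
for mouse, label in zip(clusters.mouse_ids, clusters.labels):
    print(f"  {mouse}: cluster {label}")
print("Mice with low FRP, low weight and slow righting co-cluster: the")
print("molecular readout tracks the phenotypic disease state.")
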