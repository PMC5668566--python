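"""Effect sizes for de novo protein synthesis and axonal ribosome density.

Simulates AHA fluorescence per neuron (37% planted decrease at the motor-
neuron sample sizes) and ribosome counts per axon profile (27% planted
density deficit, 30 axons per genotype), then estimates percent decreases
with Student's t tests.
"""

from polytrans import (
    compare_intensities,
    ribosome_density,
    simulate_axon_counts,
    simulate_cell_intensities,
)

cells = simulate_cell_intensities(
    percent_decrease=37.0,
    n_per_replicate_ctrl=[42, 40, 56],
    n_per_replicate_case=[43, 41, 56],
    lognormal_cv=0.4, seed=2)
eff = compare_intensities(cells)
print("AHA intensity, motor-neuron cell bodies (planted 37% decrease):")
print(f"  pooled cells    : {eff.pooled.estimate_pct:5.1f}% decrease, "
      f"t={eff.pooled.t:.2f}, p={eff.pooled.p:.2g}")
print(f"  replicate means : {eff.replicate_means.estimate_pct:5.1f}% decrease")
print(eff.per_replicate.round(2).to_string(index=False))

axons = simulate_axon_counts(control_density=50.0, percent_decrease=27.0,
                             n_axons_per_group=30, seed=2)
d = ribosome_density(axons)
print(f"\naxonal ribosome density (planted 27% deficit, n=30/genotype):")
print(f"  control {d.mean_ctrl:.1f} vs SMA {d.mean_case:.1f} ribosomes/unit area")
print(f"  estimated decrease {d.estimate_pct:.1f}%, t={d.t:.2f}, p={d.p:.2g}")
print("Both readouts estimate 100*(1 - mean(case)/mean(control)); the t test")
print("is on per-cell intensities / per-axon densities.")
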