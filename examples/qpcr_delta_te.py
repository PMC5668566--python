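"""qPCR delta-delta-Ct fold changes and log2 dTE for ribosomal-protein genes.

Simulates Ct tables where two ribosomal-protein transcripts are repressed
at the polysomal level but unchanged in total RNA (reduced translation
efficiency without a transcriptional change), then recovers fold changes
via the delta-delta-Ct method with two reference genes.
"""

from polytrans import qpcr_delta_te, qpcr_fold_change, simulate_qpcr

planted = {
    "Rps6": {"POL": 0.6, "TOT": 1.0},    # log2 dTE ~ -0.74
    "Rpl26": {"POL": 0.5, "TOT": 0.95},  # log2 dTE = -0.93
    "Eef2": {"POL": 0.8, "TOT": 0.8},    # level change, TE unchanged
}
ct = simulate_qpcr(planted, ct_noise_sd=0.15, n_biological=4,
                   n_technical=3, seed=6)

references = ["Actb", "Ppia"]
print(f"{'gene':8s} {'FC(POL)':>8s} {'FC(TOT)':>8s} {'log2dTE':>8s} {'planted':>8s}")
for gene, comps in planted.items():
    fc_pol = qpcr_fold_change(ct, gene, references, "POL")
    fc_tot = qpcr_fold_change(ct, gene, references, "TOT")
    dte = qpcr_delta_te(fc_pol, fc_tot)
    import numpy as np
    truth = np.log2(comps["POL"]) - np.log2(comps["TOT"])
    print(f"{gene:8s} {fc_pol:8.3f} {fc_tot:8.3f} {dte:+8.3f} {truth:+8.3f}")
print("\nNegative log2 dTE = fewer polysome-bound copies per total copy;")
print("Eef2 changes level but not TE, so its log2 dTE stays near zero.")
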