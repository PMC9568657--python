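"""Run-length significance threshold for pointwise tests on waveforms.

Pointwise t-tests on an ERP waveform are correlated across neighbouring
samples, so isolated "significant" samples are meaningless. The
Guthrie-Buchwald method simulates the null — here 15 subjects' AR(1)
difference-waveforms with lag-1 autocorrelation 0.9 over 125 samples —
and finds how long a run of consecutive significant samples can get by
chance at the 5% level.
"""

from hypercoh.stats import gb_threshold

thr = gb_threshold(rho=0.9, n_samples=125, n_subjects=15, alpha=0.05,
                   n_sim=20000, seed=0)
print(f"run-length threshold: {thr} samples ({thr / 250 * 1000:.0f} ms at 250 Hz)")
print("-> significant segments shorter than this are discarded as chance runs")

thr_white = gb_threshold(rho=0.0, n_samples=125, n_subjects=15, alpha=0.05,
                         n_sim=20000, seed=0)
print(f"for comparison, with uncorrelated samples: {thr_white} samples")
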