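"""Inter-brain wavelet coherence at the scalp and its statistics.

Simulates 12 dyads whose theta-band LPP-like bursts are strongly phase
coupled for fair divisions (kappa=0.9) but weakly for hyperunfair ones
(kappa=0.3), with equal burst amplitudes. For each dyad, per-trial
Morlet wavelet coherence at Pz is averaged over trials and collapsed
over 4-7 Hz; the fair-hyperunfair contrast is then tested sample-by-
sample across dyads with the run-length screen.
"""

import warnings

import numpy as np

from hypercoh.coherence import collapse_band, dyad_trial_coherence
from hypercoh.preprocess import preprocess_dyad
from hypercoh.stats import ar1_coefficient, gb_filter, gb_threshold, pointwise_paired_t
from hypercoh.synth import CouplingSpec, generate_schedule, simulate_dyad

N_DYADS = 12
conds = tuple((f, a) for f in ("fair", "hyperunfair") for a in ("agent", "pc"))
kappa = {"fair/agent": 0.9, "hyperunfair/agent": 0.3,
         "fair/pc": 0.3, "hyperunfair/pc": 0.3}

courses: dict[str, list[np.ndarray]] = {}
for d in range(N_DYADS):
    sched = generate_schedule(5, 24, conds, iti_samples=400, seed=d)
    cp = CouplingSpec(kappa=dict(kappa),
                      amp_by_fairness={"fair": 8.0, "hyperunfair": 8.0})
    es_r, es_o, _ = preprocess_dyad(
        simulate_dyad(sched, cp, channel_names=["Pz"], seed=d)
    )
    for f, a in conds:
        cond = f"{f}/{a}"
        wmap = dyad_trial_coherence(es_r, es_o, "Pz", cond)
        courses.setdefault(cond, []).append(collapse_band(wmap).values)

t_axis = es_r.time_axis
locus = np.argmin(np.abs(t_axis - 0.6))
print("mean band coherence at the burst locus (0.6 s):")
for cond in courses:
    print(f"  {cond:>18}: {np.nanmean([c[locus] for c in courses[cond]]):.3f}")

diffs = []
series = {}
for agency in ("agent", "pc"):
    a = np.stack(courses[f"fair/{agency}"])
    b = np.stack(courses[f"hyperunfair/{agency}"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series[agency] = pointwise_paired_t(a, b, time_axis=t_axis)
    diffs.append(np.nan_to_num(a - b)[:, 60:250])

rho = float(np.clip(ar1_coefficient(np.concatenate(diffs)), -0.99, 0.99))
thr = gb_threshold(rho, len(t_axis), N_DYADS, n_sim=2000, seed=0)
print(f"\nestimated AR(1) of difference courses: {rho:.3f}"
      f" -> run threshold {thr} samples")
for agency in ("agent", "pc"):
    ss = gb_filter(series[agency], thr)
    runs = int(ss.sig_filtered.sum())
    tmax = np.nanmax(np.abs(ss.t))
    print(f"  {agency:>6}: max |t| = {tmax:5.2f}, surviving significant "
          f"samples = {runs}")
print("-> the fair-vs-hyperunfair synchrony difference survives the run-")
print("   length screen only where coupling actually differs (agent)")
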