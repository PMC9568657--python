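"""Simulate a dyadic session, inject artifacts, and preprocess it.

Builds one receiver-observer dyad with a 2-block trial schedule, plants
>80 µV amplitude artifacts in known epochs of the receiver, then runs the
standard chain: 1-45 Hz zero-phase band-pass, EOG regression, epoching
with 200 ms baseline, +-80 µV rejection, and dyad intersection.
"""

import numpy as np

from hypercoh.io import DyadRecording
from hypercoh.preprocess import preprocess_dyad
from hypercoh.synth import CouplingSpec, generate_schedule, inject_artifacts, simulate_dyad

schedule = generate_schedule(n_blocks=2, trials_per_block=30, iti_samples=400, seed=0)
coupling = CouplingSpec(kappa=0.8)
dyad = simulate_dyad(schedule, coupling,
                     channel_names=["Fz", "Cz", "Pz", "vEOG"], seed=0)

contaminated_rec, truth = inject_artifacts(
    dyad.receiver, spike_amp_uv=130.0, spike_epochs=[3, 17, 41], seed=0
)
dyad = DyadRecording(receiver=contaminated_rec, observer=dyad.observer)

es_r, es_o, report = preprocess_dyad(dyad)
print(report.to_string(index=False))
rejected = [int(i) for i in np.flatnonzero(~es_r.keep_mask)]
print(f"\nplanted artifact epochs : {truth}")
print(f"rejected epochs         : {rejected}")
print(f"joint surviving trials  : {int(es_r.keep_mask.sum())}/{es_r.n_trials}")
print("-> the +-80 µV screen recovers exactly the contaminated trials, and")
print("   only trials clean for BOTH subjects enter the dyadic analysis")
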