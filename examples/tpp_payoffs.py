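"""Payoff bookkeeping for the third-party punishment game.

The dictator splits 20 points with a passive receiver (fair 10/10,
unfair 14/6, hyperunfair 18/2). The observer may spend up to 4 points to
punish: each point costs the observer 1, removes 3 from the dictator and
credits 1 to the receiver.
"""

from hypercoh.synth import FAIRNESS_LEVELS, compute_payoffs

print(f"{'condition':>12} {'p':>3} {'dictator':>9} {'receiver':>9} {'cost':>5}")
for fairness in FAIRNESS_LEVELS:
    for p in (0, 2, 4):
        d, r, c = compute_payoffs(fairness, p)
        print(f"{fairness:>12} {p:>3} {d:>9} {r:>9} {c:>5}")
print("-> maximal punishment of a hyperunfair split equalizes payoffs (6/6)")
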