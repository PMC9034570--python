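"""Forward kinetics: pool solutions and the observable intron/exon ratios.

Builds one transcript with synthesis alpha=2, processing beta=0.5 and
degradation gamma=1 (per unit time), evolves both RNA pools through a unit
labeling pulse, and shows the two intron-to-exon ratios the estimator will
later invert.
"""

import numpy as np

from ssre import (
    RateTriplet,
    labeled_solution,
    ratio_labeled,
    ratio_unlabeled,
    trajectory,
    unlabeled_solution,
)

rates = RateTriplet(alpha=2.0, beta=0.5, gamma=1.0)
T = 1.0

u0 = unlabeled_solution(rates, 0.0)
uT = unlabeled_solution(rates, T)
lT = labeled_solution(rates, T)

print(f"steady state before the pulse: premature={u0.p:.4f} mature={u0.m:.4f}")
print(f"unlabeled pool after T={T}:    premature={uT.p:.4f} mature={uT.m:.4f}")
print(f"labeled   pool after T={T}:    premature={lT.p:.4f} mature={lT.m:.4f}")
print(f"conservation: pools sum to ({uT.p + lT.p:.4f}, {uT.m + lT.m:.4f})")

a = ratio_unlabeled((rates.k, rates.gamma * T))
b = ratio_labeled((rates.k, rates.gamma * T))
print(f"\nobservable ratios at T: a=r_u={a:.6f}  b=r_l={b:.6f}")
print("(these two numbers, plus T, are all the estimator needs)")

# the path the observables trace as the pulse lengthens depends on k only
path = trajectory(rates.k, np.array([0.01, 0.1, 1.0, 10.0, 100.0]))
print("\ntrajectory for k=0.5 (gamma*T from 0.01 to 100):")
for x, (ai, bi) in zip([0.01, 0.1, 1.0, 10.0, 100.0], path):
    print(f"  gamma*T={x:6.2f}  a={ai:.4f}  b={bi:.4f}")
print("b falls from 1 toward 1/(1+k); a moves from 1/(1+k) toward 1-k.")
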