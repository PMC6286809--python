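"""Use known non-edges (true negatives) to sharpen the inference.

When some metabolite pairs are known not to interact, pinning those
Jacobian entries to zero shrinks the GA's search space. This script runs
the same noisy problem with and without a known-zero mask on the same
seeds and reports the paired effect on TPR/FPR.
"""

import numpy as np

import lyapnet as ln
from lyapnet.ga import GAConfig, PriorMask

toy = ln.make_toy_network(5, seed=3)
J = toy.parameters["J"]
truth = J != 0

D = np.full(5, 0.005)
C = ln.noisy_covariance(ln.forward_solve_covariance(J, D), noise_sd=0.01, seed=5)

# declare half of the true non-edges as prior knowledge
zeros = np.flatnonzero(~truth.reshape(-1, order="F"))
rng = np.random.default_rng(0)
known = rng.choice(zeros, size=len(zeros) // 2, replace=False)
mask = PriorMask(known_zero=frozenset(int(p) for p in known))
print(f"declaring {len(known)} of {len(zeros)} true non-edges as priors")

cfg = GAConfig(population_size=200, max_generations=200,
               lambda_grid=(0.115, 0.12, 0.125), repeats_per_lambda=2, rng_seed=0)
with_mask = ln.infer_network(covariance=C, fluctuation=D, cfg=cfg, mask=mask)
without = ln.infer_network(covariance=C, fluctuation=D, cfg=cfg)

for label, res in [("with priors   ", with_mask), ("without priors", without)]:
    ev = ln.tpr_fpr(res.structure, truth)
    print(f"{label}: TPR {ev.tpr:.2f}  FPR {ev.fpr:.2f}  g {ev.g_score:.2f}")

masked_violations = int(with_mask.structure.reshape(-1, order="F")[known].sum())
print(f"masked positions appearing as edges: {masked_violations} (always 0)")
# The mask guarantees no spurious edge at any declared position; whether the
# overall rates improve depends on whether the unconstrained run's false
# positives happen to fall inside the declared set. At benchmark scale,
# declaring even ~5% of true negatives measurably raises TPR as well
# (see lyapnet benchmark --experiment prior-knowledge).
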