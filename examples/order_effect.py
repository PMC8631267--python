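"""The generalization-order effect under the sequential process model.

LoCaLaPro commits to its own category assignments while answering: with a
small concentration alpha, a near-first task order keeps everything in the
learning category (consistent answers throughout), while a far-first order
often opens a fresh category with a prior-sampled law on the very first,
highly dissimilar task — and later tasks join it, so diversity persists.
The script simulates populations in both orders and compares their KR-21
inter-participant consistency (rho_tau); stateless models cannot produce
this gap.
"""

import causalgen as cg

table = cg.enumerate_laws(cg.exp1_grammar())
summary, matrices = cg.order_effect_experiment(
    table, alphas=(0.38,), conditions=("A1", "A3", "A5"),
    n=150, seed=0, beta=1.0, t=10.09, n_runs=150)

piv = summary.pivot_table(index="condition", columns="transfer_order",
                          values="mean_rho")
print("mean task-wise rho_tau (150 simulated participants per cell, "
      "alpha=0.38, beta=1):\n")
print(piv.round(4).to_string())
gap = (piv["near-first"] - piv["far-first"]).mean()
print(f"\nmean near-first minus far-first gap: {gap:+.4f}")
print("A positive gap on every condition reproduces the qualitative "
      "order effect:\nanswering near-transfer questions first makes "
      "simulated populations more consistent.")
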