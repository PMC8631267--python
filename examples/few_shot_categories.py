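"""Few-shot learning with ordinal features and latent causal categories.

Six learning events follow the rule "the result gains one edge over the
agent and one shade over the recipient".  When the *agent* is fixed (B1)
and categorization focuses on agents (gamma = 1), the Gibbs sampler infers
one causal category covering all six events; when the agents vary (B2),
the same focus splits the evidence into several categories, each with its
own law — the causal-asymmetry signature.
"""

from collections import Counter

import causalgen as cg
from causalgen.categories import DPParams

table = cg.enumerate_laws(cg.exp2_grammar())
params = DPParams(alpha=5.0, beta=0.5, gamma=1.0)

for condition in ("B1", "B2"):
    design = cg.exp2_design(condition, seed=0)
    fixed = "agent" if condition == "B1" else "recipient"
    state = cg.gibbs_locala(design.learning_events, params, table,
                            n_iter=500, seed=0)
    sizes = Counter(len(p.categories) for p in state.samples)
    dist = {k: round(v / len(state.samples), 2)
            for k, v in sorted(sizes.items())}
    print(f"{condition} (fixed {fixed}): posterior over number of causal "
          f"categories = {dist}")

print("\nWith a fixed agent the posterior concentrates on a single "
      "category; varied agents\nspread mass over more categories — the "
      "asymmetry that agent-focused (gamma=1)\ncategorization predicts.")

design = cg.exp2_design("B1", seed=0)
state = cg.gibbs_locala(design.learning_events, params, table,
                        n_iter=500, seed=0)
# the most learning-like scored task (lowest dissimilarity score)
task = min(design.scored_tasks,
           key=lambda t: cg.dissimilarity(t, design.learning_events).score)
pred = cg.locala_predict(state, task)
choice = pred.argmax_choice()
print(f"\nB1 generalization for {task.agent} + {task.recipient}:")
print(f"  modal prediction {choice} with probability "
      f"{pred.prob_of(choice):.2f}")
rule = cg.exp2_rule_law("B1")
truth = next(iter(rule.outcomes(task.agent, task.recipient, design.space)))
print(f"  ground-truth rule would produce {truth}")
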