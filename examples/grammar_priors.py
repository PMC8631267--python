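"""Priors over causal laws from the generative grammar.

Builds the two-feature grammar (color in {red, yellow, blue}, shape in
{circle, square, diamond}), prices a few laws by the exact product of
production probabilities, and enumerates the depth-2 table of semantically
distinct laws.  Lower prior = more productions used = more complex law:
the grammar builds a simplicity bias into causal induction.
"""

import numpy as np

import causalgen as cg

grammar = cg.exp1_grammar()
space = grammar.space

for text in (
    "(assign-not (color R') (color R))",   # result color changes
    "(assign-not (color R') blue)",        # any color but blue
    "(assign (color R') (color A))",       # result takes the agent's color
    "(and (assign (color R') (color A)) (assign (shape R') square))",
):
    law = cg.parse_law(text, space)
    print(f"P({text}) = {cg.law_prior(law, grammar):.5f}")

print(f"\nP(law conjoins more than one assertion) = "
      f"{cg.prob_more_than_k_conjuncts(grammar, 1):.2f}")

rng = np.random.default_rng(0)
sample = cg.sample_law(grammar, rng)
print(f"one sampled law: {sample}")

table = cg.enumerate_laws(grammar, max_conjuncts=2)
print(f"\ndepth-2 enumeration: {len(table)} semantically distinct laws, "
      f"renormalized prior mass {table.priors.sum():.3f}")
top = np.argsort(table.priors)[::-1][:3]
for i in top:
    print(f"  {table.priors[i]:.4f}  {table.laws[i]}")
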