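# Methods

This note documents the models implemented in `causalgen`, the choices
made where the mathematics leaves room, and what the synthetic-data
harnesses do and do not establish.

## Causal laws and their prior

A law is a conjunction of assertions, at most one per feature, each
relating the result's value of a feature to the agent's value, the
recipient's value, or a constant.  The basic relation set is `assign` and
negated assign; the ordinal extension adds `+1`, `−1`, `>` and `<`
(admissible only on ordinal features).  Generation is top-down: bind a
feature (uniformly, without replacement), decide whether to conjoin
another assertion (probability 1/2 while unbound features remain), pick a
relation (uniform over the relations admissible for the feature), then a
reference (relative vs absolute with probability 1/2 each; relative
splits evenly between agent and recipient; absolute draws a constant
uniformly from the feature's support).

Production probabilities are **context-renormalized**: at every expansion
point the choice is uniform over the productions *available there*.  The
one place this matters is the conjunction rule when no unbound feature
remains — the "bind additional" branch is unavailable and generation
stops with probability 1.  This keeps `sample_law` and `law_prior`
mutually consistent (Monte-Carlo frequencies converge to the exact
priors, verified by a χ² test) and reproduces all the standard worked
values (0.5⁵ for a relative negation, 0.5⁴·⅓ for a constant negation, a
50% conjunction rate).  A law reachable through several derivation orders
(conjuncts can be bound in either order) gets the *sum* of its derivation
probabilities.

`enumerate_laws` expands every derivation with at most `max_conjuncts`
assertions (default 2: with two-feature spaces, any deeper law is
semantically equivalent to a depth-2 one), merges semantic duplicates,
and renormalizes.  Semantic equality is decided by exhaustive truth
tables over the finite space — two laws are equal iff their outcome
domains agree on all |space|² (agent, recipient) pairs — rather than by
syntactic canonicalization, which is cheap at this scale (81 pairs in the
categorical space, 400 in the ordinal one) and robust to rewritings.

## Outcome semantics and likelihood

`D(f(a, r))` is a product over features: asserted features take the
values their assertion admits; unmentioned features keep the recipient's
value (the single most consequential semantic choice — it reads a law as
describing *changes*, everything else staying put).  A negated assertion
admits every value but the referenced one; `+1`/`−1` shift along the
ordinal order; `>`/`<` admit all strictly greater/less values.  When a
shift or inequality leaves the range (e.g. `edge(a)+1` with a 7-edge
agent), the domain is empty and the law is *inapplicable*: its likelihood
is 0 for every result.  The alternative — clamping at the boundary — was
rejected because it would manufacture deterministic predictions the
generative story never licenses; the empty-domain behavior is localized
in `Assertion.admissible_values` should a different convention be needed.

The likelihood of a complete event is uniform over the domain,
1/|D(f(a, r))|, favoring deterministic laws that nail the observed
outcome.  A "soft" variant is available as an ε-mixture with the uniform
distribution over the whole result space (`epsilon` parameter, default
0); the exact functional form of softened laws is not pinned down by the
theory, so the mixture is a labeled stand-in and no shipped analysis
depends on it.

## Categories: CRP prior, feature profiles, and three inference routes

Category structure follows a Chinese restaurant process with
concentration α > 0: an observation joins an existing category with
weight proportional to its size, or opens a new one with weight α.
Feature similarity enters through a per-category profile μ: per-feature
value counts over the members, agent values weighted γ and recipient
values 1 − γ, plus β pseudo-counts, normalized **within each feature**.
A pair's likelihood under a category is the product over features of
γ·μ_f(agent's value) + (1 − γ)·μ_f(recipient's value); a brand-new
category scores every pair with the uniform prior predictive
∏_f 1/|values_f| (the symmetric-Dirichlet predictive is uniform for every
β).  Normalizing within features — rather than pooling counts across all
feature values — makes the profile a proper categorical distribution per
feature, gives likelihood 1 to a pair identical to a single-member
category at β = 0, and turns the Gibbs conditionals into exact
Dirichlet-multinomial predictives.  γ enters as deterministic count
weighting rather than a per-category coin flip; the two readings coincide
at γ ∈ {0, 1}, which is where fits are interpreted, and the collapsed
conditionals are exactly exchangeable only there (fractional γ is an
approximation, used for smooth interpolation).

Three inference routes share this machinery:

* **Single example (exact).**  With one learning event the partition
  question collapses to "same category or new": q = CRP × feature
  likelihood, normalized, and the prediction is q × posterior-predictive
  + (1 − q) × prior-predictive, each component normalized over the
  candidate panel before mixing.  α → 0 recovers the universal model;
  large α reverts to the prior predictive.
* **Collapsed Gibbs (several examples).**  Sweeps reassign each event in
  random order, with the category law *integrated out* over the finite
  law table (the existing-category weight uses the marginal-likelihood
  ratio M_{k∪i}/M_k, the new-category weight the prior marginal M_i).
  Collapsing matters: instantiating laws for existing categories while
  marginalizing the new one is the classic invalid hybrid and produced
  measurable bias (total-variation ≈ 0.1–0.24 against two-event
  enumeration) before being replaced.  When a post-burn-in sweep is
  retained, each category's law is drawn from its exact conditional
  posterior, so retained (partition, laws) samples follow the joint.
  Defaults: single chain (a split-R-hat diagnostic over independent
  chains is available via `gibbs_rhat`), burn-in 20% of sweeps,
  singleton initialization; partitions are stored with categories relabeled by
  smallest member index so sampler-internal ids never leak.
* **Sequential process (LoCaLaPro).**  The learning events seed category
  1 with a law sampled from their posterior.  Each task is *sampled* into
  an existing category (apply its law) or a new one (law sampled from the
  prior), and the assignment is committed before the next task.  A law
  inapplicable to the committed pair yields indifference (uniform over
  the panel).  Predicted proportions are averages over independent seeded
  runs (default 1,000 in the library API; the harnesses state the sizes
  they use).

Prediction for a held-out task under the Gibbs route scores the task
against each retained partition (CRP × feature likelihood, plus the
new-category prior-predictive term) without adding it to the partition —
each task is an independent decision problem.  A joint variant (absorbing
tasks into the partition) is deliberately not offered: it would change
the exchange of information between tasks and has no validated analog.

## Choice model, fitting, and consistency

The softmax exponentiates the predictive *probabilities* times the
inverse temperature t — `exp(p·t)` renormalized; the usual log-space form
(`p^t`, i.e. softmax on log-probabilities) is available behind
`log_space=True` but is not used anywhere.  t = 0 flattens to uniform;
the log-likelihood is concave in t, so the per-grid-point 1-D
optimization is a bounded scalar search (t ∈ [0, 500]).

Fitting: the baseline has no parameters (LL = n·ln(1/m)); UnCaLa
optimizes t alone; one-example LoCaLa optimizes (α, β, t) continuously
(Nelder-Mead on log-parameters, 5 seeded multi-starts) with γ fixed at
0.5, since a single learning pair carries no signal about agent vs
recipient focus; many-example LoCaLa and LoCaLaPro use grid search
((α, β, γ) with Gibbs-estimated predictions, and (α, β) with
simulation-estimated predictions respectively), t re-optimized per grid
point.  The shipped grids are the standard protocol's (coarse α up to 8,
fine α ∈ {0.28 … 0.52}, β up to 1024, α ∈ {1 … 256} for the ordinal
experiment, γ ∈ {0, 0.25, 0.5, 0.75, 1}); callers pass reduced grids when
the full cross is not needed.  BIC uses k = free-parameter count and n =
number of scored choices (catch trials excluded).

KR-21 consistency uses the **population** variance of the aggregated
per-option counts; the sample-variance alternative can be obtained by the
caller but the statistic is reported as implemented.  A zero-variance
counts vector (every option equally popular) makes the statistic
undefined — a warning plus −inf, never a silent number.  Unanimous choice
gives exactly ρ_τ = 1 for any panel size.  Comparisons of observed
selections against uniform responding delegate to scipy's exact/χ²
contingency routines.

## Experiment designs and the synthetic generator

The categorical one-shot experiment ships as a data config
(`configs/exp1_design.json`): the anchor learning pair (red-square agent,
yellow-circle recipient), per-condition result codes (match agent /
brand-new value, per feature), and the 15-task grid in relative codes
(agent's value / recipient's value / novel value per slot).  Task 1
varies one recipient feature; the grid escalates to varying both features
of both objects, so near-first order runs 1 → 15 and far-first is its
exact reverse under the same counterbalancing seed.  The seed swaps the
color-varied/shape-varied members of each matched pair and the two
agent-feature blocks, mirroring the feature-order counterbalance.
Keeping the grid in data means a correction to any cell is a config
edit, not a code change.

The ordinal few-shot designs are generated: six varied objects form a
full cross of the feasible value sets per condition, rule-consistent,
with shade 4 and edge counts {6, 7} reserved as never-observed.  The
reservation is what makes the {match, novel} × {shade, edge} task cross
constructible and gives dissimilarity scores DS = |F_i ∖ F_L| their full
{0, 1, 2, 3} range (two novel-edge instances alternate across repeats of
a novel-edge cell).  Covering four distinct values of every varied
feature, as one might wish, is arithmetically incompatible with keeping
`+1` results inside the menu while reserving novel values — the
constrained feature covers 2–3 values instead.  Catch trials are two
seed-chosen learning events re-shown with the result hidden; the 18-task
order is randomized per seed.  The 20-option response menu (5 edges × 4
shades) is the drop-down cross, deliberately larger than the 16
observed-value configurations, so chance is 1/20.

Synthetic participants sample each choice from the softmaxed per-trial
predictive distribution of the generating model.  For LoCaLaPro that
distribution is the *run-averaged* proportion estimate — the same object
the fitting protocol softmaxes.  This matters: sampling instead from each
run's own softmaxed prediction generates data from a subtly different
observation model (softmax of a mean is not the mean of softmaxes), and
parameter recovery then misses by several grid steps.  Single-run
trajectories remain available via `localapro_run` for studying the
commitment process itself.  Participant seeds are spawned from the master
seed by index, so enlarging a simulated sample never perturbs existing
participants.

What the simulations do **not** show: simulated populations are far more
homogeneous than human ones (no lapses, no idiosyncratic priors, no
free-text-style misunderstandings), so absolute consistency levels run
high (ρ_τ ≈ 0.95 at the fitted noise scale) and order-effect gaps are
smaller than empirical ones; only directional and recovery claims should
be read off them.  Fitted-parameter values from real behavioral data are
not reproducible here and are not attempted.

## Problem sizes and tolerances

The shipped analyses run at desk scale: two-event Gibbs validation uses
25,000 sweeps (20,000 retained; TV < 0.02 against exact enumeration),
order-effect simulations use 150–200 participants per arm and 150
averaged runs per prediction matrix, and parameter recovery uses 120
simulated participants over a 7 × 3 (α, β) grid with 200 runs per grid
point, recovering α and β within one grid step and t within ~30%.
Argmax choices break ties toward the lowest canonical panel index.
Degenerate inputs are loud: a dataset no law explains raises a
degenerate-posterior error rather than returning a flat posterior, and a
candidate panel that misses predictive mass logs the lost mass before
renormalizing.

## Known limitations

Only deterministic-to-set laws are expressible (no continuous features,
no genuinely stochastic laws beyond negation/inequality ambiguity and the
ε-mixture); the Gibbs sampler is a single chain without split-merge
moves (fine at six events, untested far beyond); fractional-γ collapsed
conditionals are approximate as noted; and the grammar's production
probabilities are fixed and uniform — no grammar induction or learned Θ.
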