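"""Dirichlet-process causal categories: LoCaLa and LoCaLaPro.

A causal category is a cluster of object-pair events that share one causal
law and a mean feature profile.  The prior over partitions is a Chinese
restaurant process with concentration ``alpha``; feature similarity enters
through Dirichlet-smoothed per-feature value profiles (smoothing ``beta``)
built from agent features with weight ``gamma`` and recipient features
with weight ``1 - gamma``.

Three inference routes are provided:

* :func:`locala_single_example` — the exact two-component mixture available
  when there is a single learning event (Experiment 1);
* :func:`gibbs_locala` / :func:`locala_predict` — collapsed Gibbs sampling
  over partitions of several learning events, scoring each generalization
  task independently against the sampled partitions (Experiment 2);
* :func:`localapro_run` — the sequential process model that commits to its
  own category assignments while generalizing, which makes its predictions
  depend on task order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grammar import LawTable
from .semantics import (
    ChoiceDistribution,
    DegeneratePosteriorError,
    event_likelihood,
    mixture_choice_distribution,
    posterior_over_laws,
    predictive_matrix,
)
from .stimuli import CausalEvent, ExperimentDesign, FeatureSpace, \
    GeneralizationTask, Stone

__all__ = [
    "DPParams",
    "Category",
    "Partition",
    "GibbsState",
    "MeanFeatureProfile",
    "crp_weights",
    "category_mean",
    "pair_feature_likelihood",
    "uniform_pair_likelihood",
    "locala_single_example",
    "single_example_membership",
    "gibbs_locala",
    "locala_predict",
    "localapro_run",
    "localapro_predict",
    "dump_samples",
    "gibbs_rhat",
]


@dataclass(frozen=True)
class DPParams:
    """Global categorization parameters.

    alpha : CRP concentration (> 0); larger values favor more categories.
    beta  : Dirichlet smoothing (>= 0) on feature-value counts; larger
            values wash out feature similarity toward uniformity.
    gamma : probability mass placed on agent features when building and
            matching category profiles (1 = agent only, 0 = recipient only).
    """

    alpha: float
    beta: float = 0.0
    gamma: float = 0.5

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


@dataclass(frozen=True)
class Category:
    """Member event indices plus the category's causal law (table index)."""

    members: tuple[int, ...]
    law_index: int


@dataclass(frozen=True)
class Partition:
    """Per-event category assignments with the category list they index."""

    assignments: tuple[int, ...]
    categories: tuple[Category, ...]

    def __post_init__(self):
        for k, cat in enumerate(self.categories):
            if not cat.members:
                raise ValueError("empty categories must not be retained")
            for i in cat.members:
                if self.assignments[i] != k:
                    raise ValueError("assignments and memberships disagree")


@dataclass(frozen=True)
class GibbsState:
    """Retained partition samples from the collapsed Gibbs sampler."""

    data: tuple[CausalEvent, ...]
    params: DPParams
    table: LawTable
    samples: tuple[Partition, ...]
    n_iter: int
    burn_in: int
    seed: int

    def co_assignment(self, i: int, j: int) -> float:
        """Posterior probability that events i and j share a category."""
        if not self.samples:
            raise ValueError("no retained samples")
        hits = sum(s.assignments[i] == s.assignments[j] for s in self.samples)
        return hits / len(self.samples)


# ---------------------------------------------------------------------------
# CRP prior and feature-similarity likelihood


def crp_weights(category_sizes: Sequence[int], alpha: float) -> tuple[np.ndarray, float]:
    """Chinese-restaurant weights for one observation against the others.

    ``category_sizes`` counts the *other* assigned observations per
    existing category (so their sum is n - 1).  Returns the per-category
    weights |z_j| / (n - 1 + alpha) and the new-category weight
    alpha / (n - 1 + alpha); together they sum to 1.  With no other
    observations the first category is created with probability 1.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    sizes = np.asarray(category_sizes, dtype=float)
    denom = sizes.sum() + alpha
    return sizes / denom, float(alpha / denom)


@dataclass(frozen=True)
class MeanFeatureProfile:
    """Smoothed per-feature value distributions of a category (mu)."""

    space: FeatureSpace
    gamma: float
    probs: dict  # feature -> np.ndarray over that feature's values

    def feature_prob(self, feature: str, value) -> float:
        vals = self.space.values_of(feature)
        return float(self.probs[feature][vals.index(value)])

    def pair_likelihood(self, agent: Stone, recipient: Stone) -> float:
        """Product over features of the profile probability of the pair's
        role-weighted values (gamma on the agent, 1 - gamma on the
        recipient)."""
        g = self.gamma
        lik = 1.0
        for f in self.space.features:
            lik *= (g * self.feature_prob(f, agent.value(f))
                    + (1.0 - g) * self.feature_prob(f, recipient.value(f)))
        return lik


def category_mean(members: Sequence[CausalEvent], beta: float, gamma: float,
                  space: FeatureSpace) -> MeanFeatureProfile:
    """mu for a category: per-feature value counts over the role-weighted
    member objects (gamma x agent + (1 - gamma) x recipient), plus beta
    pseudo-counts, normalized within each feature."""
    if not members:
        raise ValueError("category has no members")
    probs = {}
    for f in space.features:
        vals = space.values_of(f)
        counts = np.full(len(vals), float(beta))
        for ev in members:
            counts[vals.index(ev.agent.value(f))] += gamma
            counts[vals.index(ev.recipient.value(f))] += 1.0 - gamma
        probs[f] = counts / counts.sum()
    return MeanFeatureProfile(space, gamma, probs)


def pair_feature_likelihood(agent: Stone, recipient: Stone,
                            mu: MeanFeatureProfile) -> float:
    """Probability of a pair's features under a category profile."""
    return mu.pair_likelihood(agent, recipient)


def uniform_pair_likelihood(space: FeatureSpace) -> float:
    """Feature likelihood of any pair under an empty (new) category: the
    symmetric-Dirichlet prior predictive is uniform for every beta."""
    lik = 1.0
    for vals in space.values:
        lik *= 1.0 / len(vals)
    return lik


class _CategoryCounts:
    """Incremental gamma-weighted feature-value counts for one category."""

    def __init__(self, space: FeatureSpace, beta: float, gamma: float):
        self.space = space
        self.beta = beta
        self.gamma = gamma
        self._idx = [{v: i for i, v in enumerate(vals)} for vals in space.values]
        self.counts = [np.zeros(len(vals)) for vals in space.values]
        self.n = 0

    def add(self, agent: Stone, recipient: Stone, sign: float = 1.0) -> None:
        g = self.gamma
        for fi in range(len(self.space.features)):
            self.counts[fi][self._idx[fi][agent.values[fi]]] += sign * g
            self.counts[fi][self._idx[fi][recipient.values[fi]]] += sign * (1.0 - g)
        self.n += 1 if sign > 0 else -1

    def remove(self, agent: Stone, recipient: Stone) -> None:
        self.add(agent, recipient, sign=-1.0)

    def pair_likelihood(self, agent: Stone, recipient: Stone) -> float:
        g = self.gamma
        b = self.beta
        lik = 1.0
        for fi in range(len(self.space.features)):
            c = self.counts[fi]
            tot = c.sum() + b * len(c)
            if tot <= 0.0:
                p_a = p_r = 1.0 / len(c)
            else:
                p_a = (c[self._idx[fi][agent.values[fi]]] + b) / tot
                p_r = (c[self._idx[fi][recipient.values[fi]]] + b) / tot
            lik *= g * p_a + (1.0 - g) * p_r
        return lik


# ---------------------------------------------------------------------------
# LoCaLa with one learning event: exact two-component mixture


def single_example_membership(learning: CausalEvent, task: GeneralizationTask,
                              params: DPParams, space: FeatureSpace) -> float:
    """P(the task pair joins the learning event's category): the CRP weight
    times the feature-similarity likelihood, normalized against the
    new-category alternative.  At gamma = 1 this depends only on the
    task's agent features."""
    existing, new = crp_weights([1], params.alpha)
    mu = category_mean([learning], params.beta, params.gamma, space)
    w_same = existing[0] * mu.pair_likelihood(task.agent, task.recipient)
    w_new = new * uniform_pair_likelihood(space)
    return w_same / (w_same + w_new)


def locala_single_example(learning: CausalEvent, task: GeneralizationTask,
                          params: DPParams, table: LawTable) -> ChoiceDistribution:
    """Exact LoCaLa prediction from a single learning event.

    The task pair either joins the learning event's category (probability
    q, from the CRP weight times feature similarity) and inherits the
    posterior over laws given the learning event, or opens a new category
    (probability 1 - q) whose law comes from the grammar prior:

        P(r') = q * posterior-predictive(r') + (1 - q) * prior-predictive(r')

    As alpha -> 0, q -> 1 and the prediction collapses to UnCaLa; as
    alpha grows the prediction reverts to the prior predictive.
    """
    q = single_example_membership(learning, task, params, table.space)
    posterior = posterior_over_laws(table, [learning])
    post_dist = mixture_choice_distribution(posterior.probs, table, task)
    prior_dist = mixture_choice_distribution(table.priors, table, task)
    probs = q * post_dist.probs + (1.0 - q) * prior_dist.probs
    return ChoiceDistribution(task.candidates, probs)


# ---------------------------------------------------------------------------
# collapsed Gibbs sampling over partitions (LoCaLa, several events)


def _likelihood_matrix(data: Sequence[CausalEvent], table: LawTable,
                       epsilon: float = 0.0) -> np.ndarray:
    """L[i, f] = P(d_i | law_f)."""
    return np.array([
        [event_likelihood(ev, law, table.space, epsilon) for law in table.laws]
        for ev in data
    ])


def _sample_index(rng: np.random.Generator, weights: np.ndarray) -> int:
    total = weights.sum()
    if total <= 0.0:
        raise DegeneratePosteriorError("all assignment weights are zero")
    return int(rng.choice(len(weights), p=weights / total))


def _canonical_partition(assign: list[int], members: dict[int, list[int]],
                         laws: dict[int, int]) -> Partition:
    """Relabel categories by smallest member index so that relabeling the
    sampler's internal ids never changes the stored partition."""
    order = sorted(members, key=lambda k: min(members[k]))
    relabel = {k: new for new, k in enumerate(order)}
    categories = tuple(
        Category(tuple(sorted(members[k])), laws[k]) for k in order
    )
    assignments = tuple(relabel[a] for a in assign)
    return Partition(assignments, categories)


def gibbs_locala(data: Sequence[CausalEvent], params: DPParams,
                 table: LawTable, n_iter: int = 2000,
                 burn_in: int | None = None, seed: int = 0,
                 epsilon: float = 0.0) -> GibbsState:
    """Collapsed Gibbs sampler over causal-category partitions.

    Each sweep reassigns every event in random (without-replacement)
    order.  An event's weight for an existing category combines the CRP
    prior, the feature likelihood of its pair under the other members'
    profile, and the marginal result likelihood under the category's law
    posterior (the law is integrated out over the finite table, so the
    chain targets the partition posterior exactly); the new-category
    weight uses the grammar-prior marginal.  After each sweep the
    per-category laws are drawn from their exact conditional posterior
    given the members, so retained (partition, laws) samples follow the
    joint posterior.  Retention starts after ``burn_in`` sweeps
    (default: 20% of ``n_iter``).
    """
    data = tuple(data)
    if not data:
        raise ValueError("need at least one event")
    if burn_in is None:
        burn_in = n_iter // 5
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng(seed)
    space = table.space
    n = len(data)
    L = _likelihood_matrix(data, table, epsilon)
    marginal = L @ table.priors  # new-category evidence per event
    if np.any(marginal <= 0.0):
        bad = int(np.argmin(marginal))
        raise DegeneratePosteriorError(f"no law explains event {bad}")
    u_feat = uniform_pair_likelihood(space)

    assign = list(range(n))  # start from singletons; burn-in mixes
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    counts = {k: _CategoryCounts(space, params.beta, params.gamma)
              for k in members}
    law_prod = {}  # per category: elementwise product of member likelihoods
    for k, ms in members.items():
        for i in ms:
            counts[k].add(data[i].agent, data[i].recipient)
        law_prod[k] = table.priors * np.prod(L[ms, :], axis=0)

    samples = []
    for sweep in range(n_iter):
        for i in rng.permutation(n):
            i = int(i)
            old = assign[i]
            members[old].remove(i)
            counts[old].remove(data[i].agent, data[i].recipient)
            if not members[old]:
                del members[old], counts[old], law_prod[old]
            else:
                law_prod[old] = table.priors * np.prod(L[members[old], :],
                                                       axis=0)

            ids = sorted(members)
            w = np.empty(len(ids) + 1)
            for j, k in enumerate(ids):
                ev_k = law_prod[k].sum()
                ev_ki = float(law_prod[k] @ L[i])
                w[j] = (len(members[k])
                        * counts[k].pair_likelihood(data[i].agent,
                                                    data[i].recipient)
                        * (ev_ki / ev_k))
            w[-1] = params.alpha * u_feat * marginal[i]
            pick = _sample_index(rng, w)
            if pick == len(ids):
                k = next_id
                next_id += 1
                members[k] = [i]
                counts[k] = _CategoryCounts(space, params.beta, params.gamma)
                law_prod[k] = table.priors * L[i]
            else:
                k = ids[pick]
                members[k].append(i)
                law_prod[k] = law_prod[k] * L[i]
            assign[i] = k
            counts[k].add(data[i].agent, data[i].recipient)
        if sweep >= burn_in:
            laws = {k: _sample_index(rng, law_prod[k]) for k in members}
            samples.append(_canonical_partition(assign, members, laws))

    return GibbsState(data, params, table, tuple(samples), n_iter, burn_in,
                      seed)


def locala_predict(state: GibbsState, task: GeneralizationTask,
                   params: DPParams | None = None) -> ChoiceDistribution:
    """LoCaLa prediction: average, over retained partition samples, of the
    category-weighted law predictions plus the new-category
    prior-predictive, treating the task as an independent decision
    problem (it is scored against each partition, never added to it)."""
    if not state.samples:
        raise ValueError("empty sample set")
    params = params or state.params
    table = state.table
    space = table.space
    u_feat = uniform_pair_likelihood(space)
    m = predictive_matrix(table, task.agent, task.recipient, task.candidates)
    prior_pred = table.priors @ m
    prior_pred = prior_pred / prior_pred.sum()

    from collections import Counter

    acc = np.zeros(len(task.candidates))
    for part, mult in Counter(state.samples).items():
        w = np.empty(len(part.categories) + 1)
        preds = []
        for k, cat in enumerate(part.categories):
            mu = category_mean([state.data[i] for i in cat.members],
                               params.beta, params.gamma, space)
            w[k] = (len(cat.members)
                    * mu.pair_likelihood(task.agent, task.recipient))
            preds.append(m[cat.law_index])
        w[-1] = params.alpha * u_feat
        w = w / w.sum()
        vec = w[-1] * prior_pred
        for k in range(len(part.categories)):
            row = preds[k]
            s = row.sum()
            if s > 0.0:
                vec = vec + w[k] * row / s
            # else: the sampled law is inapplicable to this pair; the
            # category makes no prediction and its mass is dropped
        acc += mult * vec
    acc /= acc.sum()
    return ChoiceDistribution(task.candidates, acc)


# ---------------------------------------------------------------------------
# LoCaLaPro: sequential, commitment-based categorization


def localapro_run(design: ExperimentDesign, params: DPParams,
                  table: LawTable, seed: int = 0,
                  epsilon: float = 0.0) -> tuple[list[ChoiceDistribution], Partition]:
    """One seeded run of the sequential process model.

    The learning events seed category 1 with a law sampled from their
    posterior.  Each generalization task is then assigned — sampled, not
    maximized — to an existing category (whose law is applied to predict)
    or to a new category (whose law is sampled from the grammar prior),
    and the assignment is committed before the next task.  Because early
    assignments constrain later ones, predictions depend on task order;
    repeated runs with different seeds are averaged by
    :func:`localapro_predict` to estimate predicted proportions.
    """
    rng = np.random.default_rng(seed)
    space = table.space
    u_feat = uniform_pair_likelihood(space)
    posterior = posterior_over_laws(table, design.learning_events,
                                    epsilon=epsilon)
    first_law = _sample_index(rng, posterior.probs)

    n_learn = len(design.learning_events)
    members: list[list[int]] = [list(range(n_learn))]
    laws: list[int] = [first_law]
    counts = [_CategoryCounts(space, params.beta, params.gamma)]
    for ev in design.learning_events:
        counts[0].add(ev.agent, ev.recipient)
    assignments = [0] * n_learn

    dists: list[ChoiceDistribution] = []
    for t_idx, task in enumerate(design.tasks):
        w = np.empty(len(members) + 1)
        for k in range(len(members)):
            w[k] = (len(members[k])
                    * counts[k].pair_likelihood(task.agent, task.recipient))
        w[-1] = params.alpha * u_feat
        pick = _sample_index(rng, w)
        if pick == len(members):
            members.append([])
            counts.append(_CategoryCounts(space, params.beta, params.gamma))
            laws.append(_sample_index(rng, table.priors))
        k = pick
        m = predictive_matrix(table, task.agent, task.recipient,
                              task.candidates)
        row = m[laws[k]]
        s = row.sum()
        if s > 0.0:
            probs = row / s
        else:
            # committed law inapplicable to this pair: no outcome is
            # preferred, fall back to indifference over the panel
            probs = np.full(len(task.candidates), 1.0 / len(task.candidates))
        dists.append(ChoiceDistribution(task.candidates, probs))

        members[k].append(n_learn + t_idx)
        counts[k].add(task.agent, task.recipient)
        assignments.append(k)

    categories = tuple(Category(tuple(sorted(ms)), laws[k])
                       for k, ms in enumerate(members))
    return dists, Partition(tuple(assignments), categories)


def localapro_predict(design: ExperimentDesign, params: DPParams,
                      table: LawTable, n_runs: int = 1000,
                      seed: int = 0) -> list[ChoiceDistribution]:
    """Predicted per-trial choice proportions: the average over ``n_runs``
    independent seeded runs of :func:`localapro_run`."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n_runs)
    acc = None
    for s in seeds:
        dists, _ = localapro_run(design, params, table, seed=int(s))
        vecs = [d.probs for d in dists]
        if acc is None:
            acc = [v.copy() for v in vecs]
        else:
            for a, v in zip(acc, vecs):
                a += v
    return [ChoiceDistribution(t.candidates, a / n_runs)
            for t, a in zip(design.tasks, acc)]



# ---------------------------------------------------------------------------
# sample dumps and convergence diagnostics


def dump_samples(state: GibbsState, path) -> None:
    """Write retained partition samples as JSON lines: one object per
    retained sweep with the iteration index, per-event assignments, and
    per-category law strings."""
    import json
    from pathlib import Path

    lines = []
    for idx, part in enumerate(state.samples):
        lines.append(json.dumps({
            "iteration": state.burn_in + idx,
            "assignments": list(part.assignments),
            "laws": [str(state.table.laws[c.law_index])
                     for c in part.categories],
        }))
    Path(path).write_text("\n".join(lines) + "\n")


def gibbs_rhat(data: Sequence[CausalEvent], params: DPParams,
               table: LawTable, n_chains: int = 4, n_iter: int = 500,
               seed: int = 0) -> float:
    """Split-R-hat convergence diagnostic over independent chains.

    Runs ``n_chains`` samplers from different seeds and computes the
    standard potential-scale-reduction statistic on the per-sweep number
    of categories (a scalar summary sensitive to the partition's mixing).
    Values near 1 indicate the chains agree.
    """
    if n_chains < 2:
        raise ValueError("need at least 2 chains")
    seeds = np.random.SeedSequence(seed).generate_state(n_chains)
    halves = []
    for s in seeds:
        st = gibbs_locala(data, params, table, n_iter=n_iter, seed=int(s))
        counts = np.array([len(p.categories) for p in st.samples], dtype=float)
        mid = len(counts) // 2
        halves += [counts[:mid], counts[mid:2 * mid]]
    chains = np.stack(halves)
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0.0:
        return 1.0  # all chains constant and equal
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))
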