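"""Outcome semantics of causal laws and the universal-law model (UnCaLa).

A law maps an (agent, recipient) pair to an outcome domain D(f(a, r)); the
likelihood of an observed result is uniform over that domain (1/|D| inside
it, 0 outside).  Bayesian updating over a finite law table gives a
posterior over laws, and marginalizing the posterior predictive over a
task's candidate panel gives the UnCaLa choice distribution.  UnCaLa has
no sequential state: its predictions are invariant to the order in which
generalization tasks are evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grammar import CausalLaw, LawTable
from .stimuli import CausalEvent, FeatureSpace, GeneralizationTask, Stone

__all__ = [
    "OutcomeDomain",
    "LawPosterior",
    "ChoiceDistribution",
    "DegeneratePosteriorError",
    "outcome_domain",
    "event_likelihood",
    "posterior_over_laws",
    "law_outcome_probs",
    "predictive_matrix",
    "uncala_predict",
    "posterior_to_frame",
]

logger = logging.getLogger(__name__)


class DegeneratePosteriorError(ValueError):
    """No law in the table explains the data (all likelihoods are zero)."""


@dataclass(frozen=True)
class OutcomeDomain:
    """D(f(a, r)): the set of result stones a law admits for one pair."""

    law: CausalLaw
    agent: Stone
    recipient: Stone
    outcomes: frozenset[Stone]


@dataclass(frozen=True)
class ChoiceDistribution:
    """Normalized probabilities over one task's candidate panel."""

    candidates: tuple[Stone, ...]
    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.candidates),):
            raise ValueError("probability vector does not match the panel")
        if np.any(p < -1e-12) or not np.isclose(p.sum(), 1.0):
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probs", p)

    def prob_of(self, stone: Stone) -> float:
        return float(self.probs[self.candidates.index(stone)])

    def argmax_choice(self) -> Stone:
        """Modal candidate; ties break to the lowest panel index."""
        return self.candidates[int(np.argmax(self.probs))]

    def sample(self, rng: np.random.Generator) -> Stone:
        return self.candidates[int(rng.choice(len(self.candidates), p=self.probs))]


@dataclass(frozen=True)
class LawPosterior:
    """Posterior over the laws of a table given fully observed events."""

    table: LawTable
    probs: np.ndarray
    log_evidence: float

    def prob_of(self, law: CausalLaw) -> float:
        return float(self.probs[self.table.index(law)])


def outcome_domain(law: CausalLaw, agent: Stone, recipient: Stone,
                   space: FeatureSpace) -> OutcomeDomain:
    """Compute D(f(a, r)).

    Asserted features are constrained by the law; unmentioned features keep
    the recipient's value; a negated assertion admits every value except
    the referenced one; +1/-1 shift along the ordinal order (empty domain
    when the shift leaves the range); >/< admit all strictly greater/less
    values.
    """
    return OutcomeDomain(law, agent, recipient,
                         law.outcomes(agent, recipient, space))


def event_likelihood(event: CausalEvent, law: CausalLaw, space: FeatureSpace,
                     epsilon: float = 0.0) -> float:
    """P(d | f) = 1/|D(f(a, r))| if the result lies in the domain, else 0.

    ``epsilon`` > 0 gives the "soft" variant: an epsilon-mixture with the
    uniform distribution over the whole result space, so laws are fallible
    rather than strictly deterministic.
    """
    if event.result is None:
        raise ValueError("event has no observed result")
    dom = law.outcomes(event.agent, event.recipient, space)
    hard = 1.0 / len(dom) if event.result in dom else 0.0
    if epsilon:
        return (1.0 - epsilon) * hard + epsilon / space.n_configurations
    return hard


def posterior_over_laws(table: LawTable, data: Sequence[CausalEvent],
                        epsilon: float = 0.0) -> LawPosterior:
    """Bayes over the law table: prior x product of per-event likelihoods.

    Raises :class:`DegeneratePosteriorError` when no law has positive
    likelihood for the data.
    """
    space = table.space
    weights = table.priors.copy()
    for ev in data:
        if ev.result is None:
            raise ValueError("all events must have known results")
        lik = np.array([event_likelihood(ev, law, space, epsilon)
                        for law in table.laws])
        weights = weights * lik
    evidence = weights.sum()
    if evidence <= 0.0:
        raise DegeneratePosteriorError("no law in the table explains the data")
    return LawPosterior(table, weights / evidence, float(np.log(evidence)))


def law_outcome_probs(law: CausalLaw, agent: Stone, recipient: Stone,
                      candidates: tuple[Stone, ...],
                      space: FeatureSpace) -> np.ndarray:
    """Per-candidate outcome probabilities of one law (unnormalized over
    the panel: entries sum to the domain mass the panel covers)."""
    dom = law.outcomes(agent, recipient, space)
    probs = np.zeros(len(candidates))
    if not dom:
        return probs
    p = 1.0 / len(dom)
    for i, c in enumerate(candidates):
        if c in dom:
            probs[i] = p
    return probs


class _OutcomeCache:
    """Memoizes law-by-panel outcome matrices per (agent, recipient)."""

    def __init__(self, table: LawTable):
        self.table = table
        self._cache: dict = {}

    def matrix(self, agent: Stone, recipient: Stone,
               candidates: tuple[Stone, ...]) -> np.ndarray:
        key = (agent, recipient, candidates)
        m = self._cache.get(key)
        if m is None:
            m = np.stack([
                law_outcome_probs(law, agent, recipient, candidates,
                                  self.table.space)
                for law in self.table.laws
            ])
            self._cache[key] = m
        return m


_MATRIX_CACHES: dict[int, _OutcomeCache] = {}


def predictive_matrix(table: LawTable, agent: Stone, recipient: Stone,
                      candidates: tuple[Stone, ...]) -> np.ndarray:
    """(n_laws, n_candidates) matrix of outcome probabilities, cached per
    table identity."""
    cache = _MATRIX_CACHES.get(id(table))
    if cache is None or cache.table is not table:
        cache = _OutcomeCache(table)
        _MATRIX_CACHES[id(table)] = cache
    return cache.matrix(agent, recipient, candidates)


def mixture_choice_distribution(weights: np.ndarray, table: LawTable,
                                task: GeneralizationTask) -> ChoiceDistribution:
    """Marginalize law weights over outcome probabilities, renormalized on
    the task's panel.  Logs a warning when the panel does not cover all
    positive-probability outcomes."""
    m = predictive_matrix(table, task.agent, task.recipient, task.candidates)
    raw = weights @ m
    covered = raw.sum()
    if covered <= 0.0:
        raise DegeneratePosteriorError(
            "no positive-probability outcome lies on the candidate panel")
    # mass of applicable laws whose domains the panel only partly covers
    applicable = float(weights @ (m.sum(axis=1) > 0))
    if covered < applicable - 1e-9:
        logger.warning(
            "candidate panel misses %.3g of the predictive mass",
            applicable - covered,
        )
    return ChoiceDistribution(task.candidates, raw / covered)


def uncala_predict(posterior: LawPosterior,
                   task: GeneralizationTask) -> ChoiceDistribution:
    """UnCaLa: marginalize the law posterior over each candidate outcome."""
    return mixture_choice_distribution(posterior.probs, posterior.table, task)


def posterior_to_frame(posterior: LawPosterior, data: Sequence[CausalEvent] = ()):
    """Posterior dump as a DataFrame (law string, prior, likelihood,
    posterior), CSV-ready."""
    import pandas as pd

    table = posterior.table
    liks = []
    for law in table.laws:
        lik = 1.0
        for ev in data:
            lik *= event_likelihood(ev, law, table.space)
        liks.append(lik)
    return pd.DataFrame({
        "law": [str(law) for law in table.laws],
        "prior": table.priors,
        "likelihood": liks,
        "posterior": posterior.probs,
    })
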