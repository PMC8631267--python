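"""Probabilistic context-free grammar over causal laws.

A causal law is a conjunction of feature assertions about the result stone
r'.  Each assertion binds one feature and relates it to the agent's value,
the recipient's value, or a constant, through a relation:

====================  =======================================  ============
relation              meaning for feature phi                  feature kind
====================  =======================================  ============
``assign``            phi(r') <= ref                           any
``assign_not``        phi(r') is any admissible value != ref   any
``plus_1``            phi(r') is the value one step above ref  ordinal
``minus_1``           one step below ref                       ordinal
``greater``           any value strictly above ref             ordinal
``less``              any value strictly below ref             ordinal
====================  =======================================  ============

Laws are generated top-down: bind a feature (sampled without replacement),
optionally conjoin another assertion (probability 1/2 while unbound
features remain), pick a relation, then a reference (agent/recipient value
with probability 1/4 each, or a uniformly drawn constant with total
probability 1/2).  All production probabilities are uniform over the
productions available at each step, so the prior of a law is simply the
product of its production probabilities (summed over derivation orders
when a conjunction can be built in more than one order).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .stimuli import FeatureSpace, Stone, ORDINAL

__all__ = [
    "Assertion",
    "CausalLaw",
    "Grammar",
    "LawTable",
    "exp1_grammar",
    "exp2_grammar",
    "sample_law",
    "law_prior",
    "enumerate_laws",
    "prob_more_than_k_conjuncts",
    "law_to_sexpr",
    "parse_law",
    "load_grammar",
    "dump_grammar",
]

CATEGORICAL_RELATIONS = ("assign", "assign_not")
ORDINAL_RELATIONS = ("assign", "assign_not", "plus_1", "minus_1",
                     "greater", "less")

_REL_TOKENS = {
    "assign": "assign",
    "assign_not": "assign-not",
    "plus_1": "plus-1",
    "minus_1": "minus-1",
    "greater": "greater",
    "less": "less",
}
_REL_FROM_TOKEN = {v: k for k, v in _REL_TOKENS.items()}


@dataclass(frozen=True)
class Assertion:
    """One conjunct: ``relation(feature(r'), reference)``.

    ``reference`` is ``("agent",)``, ``("recipient",)`` or
    ``("const", value)``; a relative reference always reads the *same*
    feature it asserts (the lambda binding of the grammar).
    """

    feature: str
    relation: str
    reference: tuple

    def __post_init__(self):
        if self.relation not in _REL_TOKENS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.reference[0] not in ("agent", "recipient", "const"):
            raise ValueError(f"unknown reference {self.reference!r}")

    def reference_value(self, agent: Stone, recipient: Stone):
        kind = self.reference[0]
        if kind == "agent":
            return agent.value(self.feature)
        if kind == "recipient":
            return recipient.value(self.feature)
        return self.reference[1]

    def admissible_values(self, agent: Stone, recipient: Stone,
                          space: FeatureSpace) -> tuple:
        """Result values this assertion allows for its feature (may be empty)."""
        vals = space.values_of(self.feature)
        ref = self.reference_value(agent, recipient)
        if self.relation == "assign":
            return (ref,)
        if self.relation == "assign_not":
            return tuple(v for v in vals if v != ref)
        idx = vals.index(ref)
        if self.relation == "plus_1":
            return (vals[idx + 1],) if idx + 1 < len(vals) else ()
        if self.relation == "minus_1":
            return (vals[idx - 1],) if idx - 1 >= 0 else ()
        if self.relation == "greater":
            return tuple(vals[idx + 1:])
        return tuple(vals[:idx])  # less


@dataclass(frozen=True)
class CausalLaw:
    """A conjunction of assertions, at most one per feature."""

    assertions: tuple[Assertion, ...]

    def __post_init__(self):
        feats = [a.feature for a in self.assertions]
        if len(set(feats)) != len(feats):
            raise ValueError("a law may bind each feature at most once")

    def canonical(self, space: FeatureSpace) -> "CausalLaw":
        """Assertions sorted by feature position in the space."""
        order = sorted(self.assertions,
                       key=lambda a: space.index(a.feature))
        return CausalLaw(tuple(order))

    def outcomes(self, agent: Stone, recipient: Stone,
                 space: FeatureSpace) -> frozenset[Stone]:
        """The outcome domain D(f(a, r)).

        Features the law does not mention keep the recipient's value.  An
        assertion with no admissible value (a +1/-1 reference at the edge
        of the ordinal range, or > at the maximum) makes the whole domain
        empty: the law is inapplicable to this pair.
        """
        by_feature = {a.feature: a for a in self.assertions}
        per_feature = []
        for f in space.features:
            if f in by_feature:
                allowed = by_feature[f].admissible_values(agent, recipient, space)
                if not allowed:
                    return frozenset()
                per_feature.append(allowed)
            else:
                per_feature.append((recipient.value(f),))
        return frozenset(Stone(space.features, combo)
                         for combo in itertools.product(*per_feature))

    def __str__(self):
        return law_to_sexpr(self)


@dataclass(frozen=True)
class Grammar:
    """The grammar: a feature space plus the relation set per feature kind.

    ``ordinal_relations=False`` is the Experiment 1 grammar (assign and
    negated assign only); ``True`` adds +1, -1, > and < for ordinal
    features, the Experiment 2 extension.
    """

    space: FeatureSpace
    ordinal_relations: bool = False

    def relations_for(self, feature: str) -> tuple[str, ...]:
        if self.ordinal_relations and self.space.kind_of(feature) == ORDINAL:
            return ORDINAL_RELATIONS
        return CATEGORICAL_RELATIONS


def exp1_grammar() -> Grammar:
    from .stimuli import exp1_space
    return Grammar(exp1_space(), ordinal_relations=False)


def exp2_grammar() -> Grammar:
    from .stimuli import exp2_space
    return Grammar(exp2_space(), ordinal_relations=True)


# ---------------------------------------------------------------------------
# sampling and exact priors


def _assertion_options(grammar: Grammar, feature: str) -> Iterator[tuple[Assertion, float]]:
    """All assertions bindable to ``feature`` with their derivation probability
    (relation choice x reference choice), conditional on the feature choice."""
    relations = grammar.relations_for(feature)
    p_rel = 1.0 / len(relations)
    vals = grammar.space.values_of(feature)
    for rel in relations:
        yield Assertion(feature, rel, ("agent",)), p_rel * 0.25
        yield Assertion(feature, rel, ("recipient",)), p_rel * 0.25
        for v in vals:
            yield Assertion(feature, rel, ("const", v)), p_rel * 0.5 / len(vals)


def sample_law(grammar: Grammar, rng: np.random.Generator) -> CausalLaw:
    """Sample one law by stochastically expanding from the start symbol."""
    remaining = list(grammar.space.features)
    assertions = []
    while True:
        f = remaining.pop(int(rng.integers(len(remaining))))
        relations = grammar.relations_for(f)
        rel = relations[int(rng.integers(len(relations)))]
        if rng.random() < 0.5:  # C -> D: relative reference
            ref = ("agent",) if rng.random() < 0.5 else ("recipient",)
        else:  # C -> E: absolute reference
            vals = grammar.space.values_of(f)
            ref = ("const", vals[int(rng.integers(len(vals)))])
        assertions.append(Assertion(f, rel, ref))
        # A -> and(B, S) continues while a feature is left to bind
        if not remaining or rng.random() < 0.5:
            break
    return CausalLaw(tuple(assertions))


def _derivations(grammar: Grammar,
                 max_conjuncts: int | None = None) -> Iterator[tuple[tuple[Assertion, ...], float]]:
    """Enumerate every derivation (ordered assertion sequence) with its
    probability.  Derivations cut off at ``max_conjuncts`` lose the
    continuation mass, exactly like depth-bounded enumeration."""

    def rec(remaining: tuple[str, ...], prefix: tuple[Assertion, ...], prob: float):
        p_feat = prob / len(remaining)
        for f in remaining:
            rest = tuple(x for x in remaining if x != f)
            for assertion, p_a in _assertion_options(grammar, f):
                seq = prefix + (assertion,)
                p = p_feat * p_a
                if not rest:
                    yield seq, p  # A -> B forced: no feature left to conjoin
                elif max_conjuncts is not None and len(seq) >= max_conjuncts:
                    yield seq, p * 0.5  # stop branch only; deeper mass dropped
                else:
                    yield seq, p * 0.5
                    yield from rec(rest, seq, p * 0.5)

    yield from rec(grammar.space.features, (), 1.0)


def law_prior(law: CausalLaw, grammar: Grammar) -> float:
    """Exact grammar prior of a law: the product of its production
    probabilities, summed over all derivation orders that yield it."""
    space = grammar.space
    for a in law.assertions:
        if a.relation not in grammar.relations_for(a.feature):
            raise ValueError(
                f"relation {a.relation!r} is not in the grammar for {a.feature!r}"
            )
        if a.reference[0] == "const" and a.reference[1] not in space.values_of(a.feature):
            raise ValueError(f"constant {a.reference[1]!r} outside the space")
    target = law.canonical(space).assertions
    n = len(target)
    total = 0.0
    for seq, p in _derivations(grammar, max_conjuncts=n):
        if len(seq) == n and tuple(sorted(seq, key=lambda a: space.index(a.feature))) == target:
            total += p
    return total


def prob_more_than_k_conjuncts(grammar: Grammar, k: int) -> float:
    """P(a sampled law has more than k assertions): the geometric decay of
    the 'bind additional' rule, 0.5**k, while unbound features remain."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= len(grammar.space.features):
        return 0.0
    return 0.5 ** k


# ---------------------------------------------------------------------------
# depth-bounded semantic enumeration


@dataclass(frozen=True)
class LawTable:
    """Semantically distinct laws with renormalized prior mass.

    Two laws are equivalent iff their outcome domains agree on every
    (agent, recipient) pair of the space; duplicates are merged and their
    prior mass summed, then the vector is renormalized to 1.
    """

    laws: tuple[CausalLaw, ...]
    priors: np.ndarray
    space: FeatureSpace

    def __len__(self):
        return len(self.laws)

    def index(self, law: CausalLaw) -> int:
        target = law.canonical(self.space)
        sig = _signature(target, self.space)
        for i, other in enumerate(self.laws):
            if _signature(other, self.space) == sig:
                return i
        raise KeyError(f"no semantically equal law in table: {law}")


def _signature(law: CausalLaw, space: FeatureSpace) -> tuple:
    """Truth-table signature: per (a, r) pair, the per-feature admissible
    value sets (or an EMPTY sentinel when the law is inapplicable).  Two
    laws share a signature iff their outcome domains agree everywhere."""
    stones = space.all_stones()
    by_feature = {a.feature: a for a in law.assertions}
    sig = []
    for a in stones:
        for r in stones:
            cell = []
            empty = False
            for f in space.features:
                if f in by_feature:
                    allowed = by_feature[f].admissible_values(a, r, space)
                    if not allowed:
                        empty = True
                        break
                    cell.append(frozenset(allowed))
                else:
                    cell.append(frozenset((r.value(f),)))
            sig.append("EMPTY" if empty else tuple(cell))
    return tuple(sig)


def enumerate_laws(grammar: Grammar, space: FeatureSpace | None = None,
                   max_conjuncts: int = 2) -> LawTable:
    """Enumerate all laws with at most ``max_conjuncts`` assertions, merge
    semantic duplicates (exhaustive truth-table comparison over the finite
    space), and renormalize the merged prior mass to 1.

    Any syntactically deeper law of a two-feature grammar is semantically
    equivalent to a member of the depth-2 table, so this finite table
    stands in for the full prior.
    """
    if max_conjuncts < 1:
        raise ValueError("max_conjuncts must be >= 1")
    if space is None:
        space = grammar.space

    # group derivation mass by canonical law first (cheap), then merge
    # semantic duplicates by exhaustive truth-table comparison
    syntactic: dict[tuple[Assertion, ...], float] = {}
    for seq, p in _derivations(grammar, max_conjuncts=max_conjuncts):
        key = CausalLaw(seq).canonical(space).assertions
        syntactic[key] = syntactic.get(key, 0.0) + p

    mass: dict[tuple, float] = {}
    rep: dict[tuple, CausalLaw] = {}
    for key, p in syntactic.items():
        law = CausalLaw(key)
        sig = _signature(law, space)
        if sig not in mass:
            mass[sig] = 0.0
            rep[sig] = law
        mass[sig] += p

    sigs = sorted(mass, key=lambda s: (len(rep[s].assertions), law_to_sexpr(rep[s])))
    priors = np.array([mass[s] for s in sigs], dtype=float)
    priors /= priors.sum()
    return LawTable(tuple(rep[s] for s in sigs), priors, space)


# ---------------------------------------------------------------------------
# serialization: S-expressions


def _value_token(v) -> str:
    return str(v)


def _assertion_sexpr(a: Assertion) -> str:
    if a.reference[0] == "agent":
        ref = f"({a.feature} A)"
    elif a.reference[0] == "recipient":
        ref = f"({a.feature} R)"
    else:
        ref = _value_token(a.reference[1])
    return f"({_REL_TOKENS[a.relation]} ({a.feature} R') {ref})"


def law_to_sexpr(law: CausalLaw) -> str:
    parts = [_assertion_sexpr(a) for a in law.assertions]
    if len(parts) == 1:
        return parts[0]
    return "(and " + " ".join(parts) + ")"


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list:
    return _TOKEN_RE.findall(text)


def _parse_tokens(tokens: list, pos: int):
    if tokens[pos] != "(":
        return tokens[pos], pos + 1
    items = []
    pos += 1
    while tokens[pos] != ")":
        node, pos = _parse_tokens(tokens, pos)
        items.append(node)
    return items, pos + 1


def _coerce_value(token: str, feature: str, space: FeatureSpace | None):
    if space is None:
        try:
            return int(token)
        except ValueError:
            return token
    for v in space.values_of(feature):
        if str(v) == token:
            return v
    raise ValueError(f"{token!r} is not an admissible {feature}")


def _node_to_assertion(node, space: FeatureSpace | None) -> Assertion:
    head, target, ref = node
    relation = _REL_FROM_TOKEN.get(head)
    if relation is None:
        raise ValueError(f"unknown relation token {head!r}")
    feature = target[0]
    if target[1] != "R'":
        raise ValueError("assertions must target the result R'")
    if isinstance(ref, list):
        ref_feature, role = ref
        if ref_feature != feature:
            raise ValueError("relative references must use the bound feature")
        reference = ("agent",) if role == "A" else ("recipient",)
    else:
        reference = ("const", _coerce_value(ref, feature, space))
    return Assertion(feature, relation, reference)


def parse_law(text: str, space: FeatureSpace | None = None) -> CausalLaw:
    """Parse an S-expression law string, e.g.
    ``(and (assign (color R') (color A)) (assign (shape R') square))``."""
    node, pos = _parse_tokens(_tokenize(text), 0)
    if isinstance(node, list) and node and node[0] == "and":
        assertions = tuple(_node_to_assertion(sub, space) for sub in node[1:])
    else:
        assertions = (_node_to_assertion(node, space),)
    return CausalLaw(assertions)


# ---------------------------------------------------------------------------
# grammar config files


def load_grammar(path: str | Path) -> Grammar:
    """Load a grammar config (YAML/JSON): feature declarations plus a
    ``relations`` block (``basic`` or ``ordinal``)."""
    from .stimuli import build_feature_space, load_design_config
    cfg = load_design_config(path)
    space = build_feature_space(cfg["features"])
    return Grammar(space, ordinal_relations=cfg.get("relations", "basic") == "ordinal")


def dump_grammar(grammar: Grammar, path: str | Path) -> None:
    cfg = {
        "features": {
            f: {"values": list(grammar.space.values_of(f)),
                "kind": grammar.space.kind_of(f)}
            for f in grammar.space.features
        },
        "relations": "ordinal" if grammar.ordinal_relations else "basic",
    }
    from .stimuli import dump_design_config
    dump_design_config(cfg, path)
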