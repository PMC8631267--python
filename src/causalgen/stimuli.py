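"""Feature spaces, stones, causal events, and the two experiment designs.

The experimental paradigm is a "magic stones" task: an agent stone collides
with a recipient stone and the recipient changes into a result stone.  A
learner watches one (Experiment 1) or six (Experiment 2) such interactions
and then predicts the result for novel agent/recipient pairs, choosing from
a finite candidate panel.

Experiment 1 uses two categorical features (color: red/yellow/blue, shape:
circle/square/diamond; 9 object configurations, 9**3 = 729 event triples).
Experiment 2 uses two ordinal features (shade of blue: 1-4, number of
edges: 3-7) with a 20-option response menu (5 edges x 4 shades).
"""

from __future__ import annotations

import copy
import itertools
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "FeatureSpace",
    "Stone",
    "CausalEvent",
    "GeneralizationTask",
    "ExperimentDesign",
    "DissimilarityScore",
    "build_feature_space",
    "exp1_space",
    "exp2_space",
    "exp2_observed_space",
    "exp1_design",
    "exp2_design",
    "dissimilarity",
    "load_design_config",
    "dump_design_config",
    "EXP1_CONDITIONS",
    "EXP2_CONDITIONS",
]

CATEGORICAL = "categorical"
ORDINAL = "ordinal"

EXP1_CONDITIONS = ("A1", "A2", "A3", "A4", "A5", "A6")
EXP2_CONDITIONS = ("B1", "B2", "B3", "B4")


@dataclass(frozen=True)
class FeatureSpace:
    """An ordered set of object features with their admissible values.

    Parameters
    ----------
    features
        Ordered feature names.
    values
        Per-feature tuple of admissible values, aligned with ``features``.
        Ordinal features must list values in their natural order.
    kinds
        Per-feature kind, ``"categorical"`` or ``"ordinal"``.
    """

    features: tuple[str, ...]
    values: tuple[tuple, ...]
    kinds: tuple[str, ...]

    def __post_init__(self):
        if len(self.features) < 1:
            raise ValueError("a feature space needs at least one feature")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature names")
        if not (len(self.features) == len(self.values) == len(self.kinds)):
            raise ValueError("features, values and kinds must align")
        for name, vals, kind in zip(self.features, self.values, self.kinds):
            if len(vals) < 2:
                raise ValueError(f"feature {name!r} needs >= 2 values")
            if len(set(vals)) != len(vals):
                raise ValueError(f"feature {name!r} has duplicate values")
            if kind not in (CATEGORICAL, ORDINAL):
                raise ValueError(f"unknown feature kind {kind!r}")

    def index(self, feature: str) -> int:
        return self.features.index(feature)

    def values_of(self, feature: str) -> tuple:
        return self.values[self.index(feature)]

    def kind_of(self, feature: str) -> str:
        return self.kinds[self.index(feature)]

    @property
    def n_configurations(self) -> int:
        """Number of distinct per-object configurations."""
        n = 1
        for vals in self.values:
            n *= len(vals)
        return n

    @property
    def n_triples(self) -> int:
        """Number of distinct (agent, recipient, result) configurations."""
        return self.n_configurations ** 3

    def stone(self, **feature_values) -> "Stone":
        """Build a validated stone from feature=value keyword arguments."""
        vals = []
        for name, admissible in zip(self.features, self.values):
            if name not in feature_values:
                raise ValueError(f"missing feature {name!r}")
            v = feature_values[name]
            if v not in admissible:
                raise ValueError(
                    f"{v!r} is not an admissible {name}; choose from {admissible}"
                )
            vals.append(v)
        extra = set(feature_values) - set(self.features)
        if extra:
            raise ValueError(f"unknown features: {sorted(extra)}")
        return Stone(self.features, tuple(vals))

    def all_stones(self) -> tuple["Stone", ...]:
        """All configurations, in canonical (row-major) order."""
        return tuple(
            Stone(self.features, combo)
            for combo in itertools.product(*self.values)
        )


@dataclass(frozen=True)
class Stone:
    """An object as an immutable feature-value map."""

    features: tuple[str, ...]
    values: tuple

    def value(self, feature: str):
        return self.values[self.features.index(feature)]

    def items(self):
        return zip(self.features, self.values)

    def __repr__(self):
        body = ", ".join(f"{f}={v}" for f, v in self.items())
        return f"Stone({body})"


@dataclass(frozen=True)
class CausalEvent:
    """One interaction: agent acts on recipient, recipient becomes result.

    ``result`` is ``None`` for a partial data point (a*, r*, .), i.e. a
    generalization query whose outcome is unknown.
    """

    agent: Stone
    recipient: Stone
    result: Stone | None = None

    def __post_init__(self):
        feats = self.agent.features
        if self.recipient.features != feats:
            raise ValueError("agent and recipient live in different spaces")
        if self.result is not None and self.result.features != feats:
            raise ValueError("result lives in a different space")


@dataclass(frozen=True)
class GeneralizationTask:
    """A query pair plus the finite panel of candidate result stones."""

    agent: Stone
    recipient: Stone
    candidates: tuple[Stone, ...]
    is_catch: bool = False

    def __post_init__(self):
        if not self.candidates:
            raise ValueError("candidate panel is empty")
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError("candidate panel contains duplicates")

    @property
    def pair(self) -> CausalEvent:
        return CausalEvent(self.agent, self.recipient)


@dataclass(frozen=True)
class ExperimentDesign:
    """Learning events plus an ordered sequence of generalization tasks."""

    condition: str
    space: FeatureSpace
    learning_events: tuple[CausalEvent, ...]
    tasks: tuple[GeneralizationTask, ...]
    transfer_order: str  # near-first | far-first | randomized

    @property
    def scored_tasks(self) -> tuple[GeneralizationTask, ...]:
        return tuple(t for t in self.tasks if not t.is_catch)


@dataclass(frozen=True)
class DissimilarityScore:
    """|F_i \\ F_L|: count of (feature, value) pairs in a trial never seen
    on any object during learning."""

    learning_values: frozenset
    trial_values: frozenset
    score: int


# ---------------------------------------------------------------------------
# construction helpers


def build_feature_space(config: dict) -> FeatureSpace:
    """Build a :class:`FeatureSpace` from a declaration mapping.

    ``config`` maps feature name -> ``{"values": [...], "kind": ...}``
    (kind defaults to categorical).
    """
    names, values, kinds = [], [], []
    for name, decl in config.items():
        names.append(name)
        values.append(tuple(decl["values"]))
        kinds.append(decl.get("kind", CATEGORICAL))
    return FeatureSpace(tuple(names), tuple(values), tuple(kinds))


def exp1_space() -> FeatureSpace:
    return FeatureSpace(
        ("color", "shape"),
        (("red", "yellow", "blue"), ("circle", "square", "diamond")),
        (CATEGORICAL, CATEGORICAL),
    )


def exp2_space() -> FeatureSpace:
    """Full Experiment 2 space: 4 shades x 5 edge counts (the response menu)."""
    return FeatureSpace(
        ("shade", "edge"),
        ((1, 2, 3, 4), (3, 4, 5, 6, 7)),
        (ORDINAL, ORDINAL),
    )


def exp2_observed_space() -> FeatureSpace:
    """The 4 x 4 observed-value subspace (16 configurations, 16**3 triples).

    Edge counts 4-7 are taken as the observed values; triangles (3 edges)
    only occur on the drop-down response menu.
    """
    return FeatureSpace(
        ("shade", "edge"),
        ((1, 2, 3, 4), (4, 5, 6, 7)),
        (ORDINAL, ORDINAL),
    )


# ---------------------------------------------------------------------------
# shipped Experiment 1 design config (the Fig-3-style task grid lives in
# data, not code, so it can be corrected against the figure without a code
# change)

_EXP1_CONFIG_CACHE: dict | None = None


def _exp1_config() -> dict:
    global _EXP1_CONFIG_CACHE
    if _EXP1_CONFIG_CACHE is None:
        text = resources.files("causalgen").joinpath("configs/exp1_design.json").read_text()
        _EXP1_CONFIG_CACHE = json.loads(text)
    return copy.deepcopy(_EXP1_CONFIG_CACHE)


def load_design_config(path: str | Path) -> dict:
    """Load a design config (JSON or YAML) as a plain mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def dump_design_config(config: dict, path: str | Path) -> None:
    """Write a design config; ``load -> dump -> load`` is the identity."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=False))
    else:
        path.write_text(json.dumps(config, indent=2) + "\n")


def _resolve_code(code: str, feature: str, agent: Stone, recipient: Stone,
                  novel: dict):
    if code == "a":
        return agent.value(feature)
    if code == "r":
        return recipient.value(feature)
    if code == "n":
        return novel[feature]
    raise ValueError(f"unknown grid code {code!r}")


def exp1_design(condition: str, transfer_order: str = "near-first",
                feature_order_seed: int = 0,
                config: dict | None = None) -> ExperimentDesign:
    """Build an Experiment 1 design: 1 learning event + 15 ordered tasks.

    ``transfer_order`` is ``"near-first"`` (tasks 1..15, increasingly
    dissimilar to the learning example) or ``"far-first"`` (the exact
    reverse).  ``feature_order_seed`` drives the counterbalancing of
    whether color-varied or shape-varied tasks come first within each
    matched pair/block of the grid.
    """
    cfg = config if config is not None else _exp1_config()
    if condition not in cfg["conditions"]:
        raise ValueError(f"unknown condition {condition!r}")
    if transfer_order not in ("near-first", "far-first"):
        raise ValueError(f"unknown transfer order {transfer_order!r}")

    space = build_feature_space(cfg["features"])
    agent = space.stone(**cfg["anchor"]["agent"])
    recipient = space.stone(**cfg["anchor"]["recipient"])
    novel = {}
    for f in space.features:
        seen = {agent.value(f), recipient.value(f)}
        remaining = [v for v in space.values_of(f) if v not in seen]
        novel[f] = remaining[0]

    result_codes = cfg["conditions"][condition]["result"]
    result = space.stone(**{
        f: _resolve_code(code, f, agent, recipient, novel)
        for f, code in zip(space.features, result_codes)
    })
    learning = CausalEvent(agent, recipient, result)

    panel = space.all_stones()
    tasks = []
    for entry in cfg["task_grid"]:
        t_agent = space.stone(**{
            f: _resolve_code(c, f, agent, recipient, novel)
            for f, c in zip(space.features, entry["agent"])
        })
        t_recipient = space.stone(**{
            f: _resolve_code(c, f, agent, recipient, novel)
            for f, c in zip(space.features, entry["recipient"])
        })
        tasks.append(GeneralizationTask(t_agent, t_recipient, panel))

    rng = np.random.default_rng(feature_order_seed)
    for i, j in cfg["counterbalance_pairs"]:
        if rng.random() < 0.5:
            tasks[i], tasks[j] = tasks[j], tasks[i]
    if rng.random() < 0.5:
        for i, j in cfg["counterbalance_blocks"]:
            tasks[i], tasks[j] = tasks[j], tasks[i]

    if transfer_order == "far-first":
        tasks = tasks[::-1]

    return ExperimentDesign(condition, space, (learning,), tuple(tasks),
                            transfer_order)


# ---------------------------------------------------------------------------
# Experiment 2


def exp2_rule_law(condition: str):
    """Ground-truth law of an Experiment 2 condition, as a CausalLaw.

    Rule 1 (B1/B2): edge(r') <= edge(a) + 1 and shade(r') <= shade(r) + 1.
    Rule 2 (B3/B4): shade(r') <= shade(a) + 1 and edge(r') <= edge(r) + 1.
    """
    from .grammar import Assertion, CausalLaw  # local import to avoid a cycle

    if condition in ("B1", "B2"):
        assertions = (
            Assertion("shade", "plus_1", ("recipient",)),
            Assertion("edge", "plus_1", ("agent",)),
        )
    elif condition in ("B3", "B4"):
        assertions = (
            Assertion("shade", "plus_1", ("agent",)),
            Assertion("edge", "plus_1", ("recipient",)),
        )
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return CausalLaw(assertions)


# Per condition: admissible values for the fixed object (seed picks one
# combination) and the value cross generating the 6 varied objects.  The
# ranges keep every result inside the menu while reserving shade 4 and
# edges {6, 7} as never-observed, so novel-value generalization tasks and
# dissimilarity scores up to 3 remain constructible.
_EXP2_PLAN = {
    #          fixed role   fixed shade     fixed edge   varied shades  varied edges
    "B1": ("agent", (1, 2, 3), (4,), (1, 2), (3, 4, 5)),
    "B2": ("recipient", (1, 2), (3,), (1, 2, 3), (3, 4)),
    "B3": ("agent", (1, 2), (3, 4, 5), (1, 2, 3), (3, 4)),
    "B4": ("recipient", (1, 2, 3), (3, 4), (1, 2), (3, 4, 5)),
}

_EXP2_NOVEL_SHADE = 4
_EXP2_NOVEL_EDGES = (6, 7)


def exp2_design(condition: str, seed: int = 0) -> ExperimentDesign:
    """Build an Experiment 2 design: 6 learning events + 16 tasks + 2 catch.

    Conditions fix the evidence balance (fixed-agent B1/B3 vs
    fixed-recipient B2/B4) and the ground-truth rule (Rule 1 for B1/B2,
    Rule 2 for B3/B4).  All learning events are outcome-consistent with
    the condition's rule; the generator only uses stimuli whose results
    stay inside the observed value ranges.  The 16 scored tasks cross
    {match, novel} on shade and edge for the fixed and the varied object;
    the two catch trials are learning events re-shown with the result
    hidden.  Task order is randomized (seed-controlled).
    """
    from .semantics import outcome_domain

    if condition not in _EXP2_PLAN:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    space = exp2_space()
    fixed_role, f_shades, f_edges, v_shades, v_edges = _EXP2_PLAN[condition]
    rule = exp2_rule_law(condition)

    fixed = space.stone(shade=int(rng.choice(f_shades)),
                        edge=int(rng.choice(f_edges)))
    varied = [space.stone(shade=s, edge=e)
              for s, e in itertools.product(v_shades, v_edges)]
    rng.shuffle(varied)

    events = []
    for v in varied:
        agent, recipient = (fixed, v) if fixed_role == "agent" else (v, fixed)
        dom = outcome_domain(rule, agent, recipient, space)
        if len(dom.outcomes) != 1:
            raise ValueError(
                "rule application left the observed value range for "
                f"agent={agent} recipient={recipient}"
            )
        events.append(CausalEvent(agent, recipient, next(iter(dom.outcomes))))

    # machine check: the reserved novel values never appear during learning
    seen = _learning_values(events)
    assert ("shade", _EXP2_NOVEL_SHADE) not in seen
    assert all(("edge", e) not in seen for e in _EXP2_NOVEL_EDGES)

    panel = space.all_stones()
    v0 = varied[int(rng.integers(len(varied)))]
    novel_edge_cycle = itertools.cycle(_EXP2_NOVEL_EDGES)

    def variant(base: Stone, novel_shade: bool, novel_edge: bool) -> Stone:
        return space.stone(
            shade=_EXP2_NOVEL_SHADE if novel_shade else base.value("shade"),
            edge=next(novel_edge_cycle) if novel_edge else base.value("edge"),
        )

    combos = [(False, False), (False, True), (True, False), (True, True)]
    tasks = []
    for f_ns, f_ne in combos:
        for v_ns, v_ne in combos:
            fx = variant(fixed, f_ns, f_ne)
            vx = variant(v0, v_ns, v_ne)
            agent, recipient = (fx, vx) if fixed_role == "agent" else (vx, fx)
            tasks.append(GeneralizationTask(agent, recipient, panel))

    catch_idx = rng.choice(len(events), size=2, replace=False)
    for i in sorted(int(i) for i in catch_idx):
        ev = events[i]
        tasks.append(GeneralizationTask(ev.agent, ev.recipient, panel,
                                        is_catch=True))

    order = rng.permutation(len(tasks))
    tasks = [tasks[i] for i in order]
    return ExperimentDesign(condition, space, tuple(events), tuple(tasks),
                            "randomized")


# ---------------------------------------------------------------------------
# dissimilarity score


def _learning_values(events: Iterable[CausalEvent]) -> frozenset:
    vals = set()
    for ev in events:
        stones = [ev.agent, ev.recipient]
        if ev.result is not None:
            stones.append(ev.result)
        for stone in stones:
            vals.update(stone.items())
    return frozenset(vals)


def dissimilarity(task: GeneralizationTask,
                  learning: Sequence[CausalEvent]) -> DissimilarityScore:
    """Count the (feature, value) pairs of a trial never observed in learning.

    ``F_L`` pools the values of every object (agent, recipient and result)
    shown during learning; ``F_i`` pools the values of the trial's agent
    and recipient.  The score is ``|F_i \\ F_L|``.
    """
    learning = list(learning)
    if not learning:
        raise ValueError("empty learning set")
    f_l = _learning_values(learning)
    f_i = frozenset(itertools.chain(task.agent.items(), task.recipient.items()))
    return DissimilarityScore(f_l, f_i, len(f_i - f_l))
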