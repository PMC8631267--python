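"""Grammar priors, sampling, depth-bounded enumeration, serialization."""

import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats

import causalgen as cg
from causalgen.grammar import _derivations


def law(text, space):
    return cg.parse_law(text, space)


class TestLawPrior:
    def test_worked_examples(self, exp1_grammar, exp1_sp):
        # result color differs from the recipient's: five binary choices
        p = cg.law_prior(law("(assign-not (color R') (color R))", exp1_sp),
                         exp1_grammar)
        assert p == pytest.approx(0.5 ** 5)
        # result color is anything but the constant blue
        p = cg.law_prior(law("(assign-not (color R') blue)", exp1_sp),
                         exp1_grammar)
        assert p == pytest.approx(0.5 ** 4 / 3)
        # result takes the agent's color: same shape as the negation walk
        p = cg.law_prior(law("(assign (color R') (color A))", exp1_sp),
                         exp1_grammar)
        assert p == pytest.approx(0.5 ** 5)

    def test_conjunction_sums_over_derivation_orders(self, exp1_grammar, exp1_sp):
        conj = law("(and (assign (color R') (color A)) "
                   "(assign (shape R') square))", exp1_sp)
        # per-assertion terms: relation 1/2, then agent reference 1/2 * 1/2
        # or constant 1/2 * 1/3; either feature can be bound first, and the
        # second binding is forced (no feature left, A -> B fires surely)
        color_part = 0.5 * (0.5 * 0.5)      # assign, agent reference
        shape_part = 0.5 * (0.5 * (1 / 3))  # assign, constant square
        one_order = (0.5 * 0.5 * color_part) * (1.0 * 1.0 * shape_part)
        assert cg.law_prior(conj, exp1_grammar) == pytest.approx(2 * one_order)

    def test_total_derivation_mass_is_one(self, exp1_grammar):
        total = sum(p for _, p in _derivations(exp1_grammar))
        assert total == pytest.approx(1.0)

    def test_relation_absent_from_grammar(self, exp1_grammar, exp1_sp):
        bad = cg.CausalLaw((cg.Assertion("color", "greater", ("agent",)),))
        with pytest.raises(ValueError, match="relation"):
            cg.law_prior(bad, exp1_grammar)

    def test_constant_outside_space(self, exp1_grammar):
        bad = cg.CausalLaw((cg.Assertion("color", "assign", ("const", "teal")),))
        with pytest.raises(ValueError, match="outside"):
            cg.law_prior(bad, exp1_grammar)


class TestSampling:
    def test_seeded_determinism(self, exp1_grammar):
        a = cg.sample_law(exp1_grammar, np.random.default_rng(99))
        b = cg.sample_law(exp1_grammar, np.random.default_rng(99))
        assert a == b

    def test_frequencies_converge_to_priors(self, exp1_grammar, exp1_sp):
        """Monte-Carlo law frequencies match the exact derivation-summed
        prior (chi-square goodness of fit, fixed seed)."""
        rng = np.random.default_rng(0)
        n = 20_000
        counts = Counter(
            cg.sample_law(exp1_grammar, rng).canonical(exp1_sp).assertions
            for _ in range(n))
        exact = {}
        for seq, p in _derivations(exp1_grammar):
            key = cg.CausalLaw(seq).canonical(exp1_sp).assertions
            exact[key] = exact.get(key, 0.0) + p
        obs = np.array([counts.get(k, 0) for k in exact])
        expected = np.array([exact[k] * n for k in exact])
        chi2 = ((obs - expected) ** 2 / expected).sum()
        p_value = stats.chi2.sf(chi2, len(exact) - 1)
        assert p_value > 0.001

    def test_conjunct_decay(self, exp1_grammar):
        assert cg.prob_more_than_k_conjuncts(exp1_grammar, 1) == 0.5
        # with only two features a third conjunct is impossible
        assert cg.prob_more_than_k_conjuncts(exp1_grammar, 2) == 0.0
        three = cg.Grammar(cg.build_feature_space({
            "a": {"values": [0, 1]}, "b": {"values": [0, 1]},
            "c": {"values": [0, 1]}}))
        assert cg.prob_more_than_k_conjuncts(three, 1) == 0.5
        assert cg.prob_more_than_k_conjuncts(three, 2) == 0.25
        rng = np.random.default_rng(1)
        n = 20_000
        more = sum(len(cg.sample_law(three, rng).assertions) > 2
                   for _ in range(n))
        assert more / n == pytest.approx(0.25, abs=0.01)


# ---------------------------------------------------------------------------
# independent brute-force oracle for the depth-2 enumeration: expands every
# derivation with explicit loops and evaluates semantics on plain dicts


def _oracle_table(vals_by_feature):
    feats = list(vals_by_feature)

    def assertion_opts(f):
        vals = vals_by_feature[f]
        for rel in ("assign", "assign_not"):
            yield (f, rel, "agent"), 0.5 * 0.25
            yield (f, rel, "recipient"), 0.5 * 0.25
            for v in vals:
                yield (f, rel, ("const", v)), 0.5 * 0.5 / len(vals)

    def derivations():
        # single assertion (stop branch) and both two-assertion orders
        for f in feats:
            rest = [x for x in feats if x != f]
            for a1, p1 in assertion_opts(f):
                base = p1 / len(feats)
                yield (a1,), base * 0.5
                for f2 in rest:
                    for a2, p2 in assertion_opts(f2):
                        yield (a1, a2), base * 0.5 * p2 / len(rest)

    def outcome_set(assertions, agent, recipient):
        per = {f: {recipient[f]} for f in feats}
        for f, rel, ref in assertions:
            refv = (agent[f] if ref == "agent"
                    else recipient[f] if ref == "recipient" else ref[1])
            if rel == "assign":
                per[f] = {refv}
            else:
                per[f] = set(vals_by_feature[f]) - {refv}
        return frozenset(itertools.product(
            *[tuple(sorted(per[f])) for f in feats]))

    objects = [dict(zip(feats, combo))
               for combo in itertools.product(*vals_by_feature.values())]

    def signature(assertions):
        return tuple(outcome_set(assertions, a, r)
                     for a in objects for r in objects)

    mass = {}
    for seq, p in derivations():
        sig = signature(seq)
        mass[sig] = mass.get(sig, 0.0) + p
    total = sum(mass.values())
    return {sig: m / total for sig, m in mass.items()}


class TestEnumeration:
    def test_matches_brute_force_oracle(self):
        vals = {"color": ("red", "blue"), "shape": ("cube", "ball")}
        space = cg.build_feature_space(
            {f: {"values": list(v)} for f, v in vals.items()})
        table = cg.enumerate_laws(cg.Grammar(space))
        oracle = _oracle_table(vals)
        assert len(table) == len(oracle)
        # match each table law to the oracle signature and compare masses
        objects = [dict(zip(vals, c))
                   for c in itertools.product(*vals.values())]
        for l, prior in zip(table.laws, table.priors):
            sig = tuple(
                frozenset(tuple(s.values) for s in
                          l.outcomes(space.stone(**a), space.stone(**r), space))
                for a in objects for r in objects)
            assert prior == pytest.approx(oracle[sig])

    def test_priors_sum_to_one(self, exp1_table, exp2_table):
        assert exp1_table.priors.sum() == pytest.approx(1.0)
        assert exp2_table.priors.sum() == pytest.approx(1.0)

    def test_expected_laws_present(self, exp1_table, exp1_sp):
        for text in ("(assign (color R') (color A))",
                     "(assign (color R') blue)"):
            i = exp1_table.index(law(text, exp1_sp))
            assert exp1_table.priors[i] > 0

    def test_semantic_duplicates_merged(self, exp1_table, exp1_sp):
        # keeping the recipient's color is the identity law, however written
        i = exp1_table.index(law("(assign (color R') (color R))", exp1_sp))
        j = exp1_table.index(law("(assign (shape R') (shape R))", exp1_sp))
        assert i == j

    def test_feature_order_is_irrelevant(self, exp1_table):
        flipped_space = cg.FeatureSpace(
            ("shape", "color"),
            (("circle", "square", "diamond"), ("red", "yellow", "blue")),
            ("categorical", "categorical"),
        )
        flipped = cg.enumerate_laws(cg.Grammar(flipped_space))
        assert len(flipped) == len(exp1_table)
        assert np.allclose(sorted(flipped.priors), sorted(exp1_table.priors))

    def test_max_conjuncts_validation(self, exp1_grammar):
        with pytest.raises(ValueError):
            cg.enumerate_laws(exp1_grammar, max_conjuncts=0)


class TestSerialization:
    def test_round_trip_preserves_semantics_and_prior(self, exp1_grammar,
                                                      exp1_table, exp1_sp):
        for l in exp1_table.laws:
            back = cg.parse_law(cg.law_to_sexpr(l), exp1_sp)
            assert back.canonical(exp1_sp) == l.canonical(exp1_sp)
            assert cg.law_prior(back, exp1_grammar) == \
                pytest.approx(cg.law_prior(l, exp1_grammar))

    def test_ordinal_relations_round_trip(self, exp2_grammar):
        sp = exp2_grammar.space
        for text in ("(plus-1 (edge R') (edge A))",
                     "(greater (shade R') 2)",
                     "(and (minus-1 (edge R') (edge R)) (less (shade R') (shade A)))"):
            l = cg.parse_law(text, sp)
            assert cg.parse_law(cg.law_to_sexpr(l), sp) == l

    def test_grammar_config_round_trip(self, tmp_path, exp2_grammar):
        path = tmp_path / "grammar.yaml"
        cg.dump_grammar(exp2_grammar, path)
        loaded = cg.load_grammar(path)
        assert loaded == exp2_grammar
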