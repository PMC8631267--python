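"""CRP weights, feature profiles, LoCaLa inference, LoCaLaPro process."""

import numpy as np
import pytest

import causalgen as cg
from causalgen.categories import DPParams, _CategoryCounts, category_mean, \
    crp_weights, uniform_pair_likelihood
from causalgen.semantics import event_likelihood, mixture_choice_distribution


@pytest.fixture(scope="module")
def learning_event():
    sp = cg.exp1_space()
    return cg.CausalEvent(
        sp.stone(color="blue", shape="square"),
        sp.stone(color="red", shape="diamond"),
        sp.stone(color="blue", shape="diamond"),
    )


class TestCRP:
    def test_first_observation_opens_first_category(self):
        existing, new = crp_weights([], 2.0)
        assert existing.size == 0 and new == 1.0

    def test_alpha5_against_five_others(self):
        existing, new = crp_weights([2, 2, 1], 5.0)
        assert new == pytest.approx(0.5)

    def test_alpha1_one_existing_member(self):
        existing, new = crp_weights([1], 1.0)
        assert existing[0] == pytest.approx(0.5)
        assert new == pytest.approx(0.5)

    def test_weights_sum_to_one_and_grow_with_size(self):
        existing, new = crp_weights([3, 1, 2], 0.7)
        assert existing.sum() + new == pytest.approx(1.0)
        assert existing[0] > existing[2] > existing[1]

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            crp_weights([1], 0.0)
        with pytest.raises(ValueError):
            DPParams(-1.0)


class TestCategoryMean:
    def test_gamma_one_ignores_recipients(self, learning_event):
        sp = cg.exp1_space()
        other = cg.CausalEvent(learning_event.agent,
                               sp.stone(color="yellow", shape="circle"))
        mu_a = category_mean([learning_event], 0.5, 1.0, sp)
        mu_b = category_mean([other], 0.5, 1.0, sp)
        for f in sp.features:
            assert np.allclose(mu_a.probs[f], mu_b.probs[f])

    def test_gamma_zero_ignores_agents(self, learning_event):
        sp = cg.exp1_space()
        other = cg.CausalEvent(sp.stone(color="yellow", shape="circle"),
                               learning_event.recipient)
        mu_a = category_mean([learning_event], 0.5, 0.0, sp)
        mu_b = category_mean([other], 0.5, 0.0, sp)
        for f in sp.features:
            assert np.allclose(mu_a.probs[f], mu_b.probs[f])

    def test_single_member_no_smoothing_is_point_mass(self, learning_event):
        sp = cg.exp1_space()
        mu = category_mean([learning_event], 0.0, 1.0, sp)
        assert mu.feature_prob("color", "blue") == 1.0
        assert mu.feature_prob("shape", "square") == 1.0


class TestPairLikelihood:
    def test_identical_pair_beta_zero(self, learning_event):
        sp = cg.exp1_space()
        mu = category_mean([learning_event], 0.0, 1.0, sp)
        assert mu.pair_likelihood(learning_event.agent,
                                  learning_event.recipient) == 1.0

    def test_shared_features_raise_likelihood(self, learning_event):
        sp = cg.exp1_space()
        mu = category_mean([learning_event], 0.5, 1.0, sp)
        near = sp.stone(color="red", shape="square")    # shares the shape
        far = sp.stone(color="yellow", shape="diamond")  # shares nothing
        r = learning_event.recipient
        assert mu.pair_likelihood(near, r) > mu.pair_likelihood(far, r)

    def test_large_beta_approaches_uniform(self, learning_event):
        sp = cg.exp1_space()
        mu = category_mean([learning_event], 1e6, 1.0, sp)
        u = uniform_pair_likelihood(sp)
        probe = sp.stone(color="yellow", shape="circle")
        assert mu.pair_likelihood(probe, probe) == pytest.approx(u, rel=1e-4)

    def test_incremental_counts_match_category_mean(self, learning_event):
        sp = cg.exp1_space()
        events = [learning_event,
                  cg.CausalEvent(sp.stone(color="red", shape="square"),
                                 sp.stone(color="red", shape="circle"))]
        counts = _CategoryCounts(sp, 0.3, 0.7)
        for ev in events:
            counts.add(ev.agent, ev.recipient)
        mu = category_mean(events, 0.3, 0.7, sp)
        probe_a = sp.stone(color="blue", shape="circle")
        probe_r = sp.stone(color="yellow", shape="diamond")
        assert counts.pair_likelihood(probe_a, probe_r) == \
            pytest.approx(mu.pair_likelihood(probe_a, probe_r))


class TestLocalaSingleExample:
    def test_alpha_to_zero_recovers_uncala(self, exp1_table, learning_event):
        sp = exp1_table.space
        task = cg.GeneralizationTask(sp.stone(color="red", shape="square"),
                                     sp.stone(color="yellow", shape="circle"),
                                     sp.all_stones())
        post = cg.posterior_over_laws(exp1_table, [learning_event])
        uncala = cg.uncala_predict(post, task)
        local = cg.locala_single_example(learning_event, task,
                                         DPParams(1e-12, 0.5, 0.5), exp1_table)
        assert np.allclose(local.probs, uncala.probs)

    def test_large_alpha_reverts_to_prior(self, exp1_table, learning_event):
        sp = exp1_table.space
        task = cg.GeneralizationTask(sp.stone(color="yellow", shape="circle"),
                                     sp.stone(color="red", shape="square"),
                                     sp.all_stones())
        prior_pred = mixture_choice_distribution(exp1_table.priors,
                                                 exp1_table, task)
        local = cg.locala_single_example(learning_event, task,
                                         DPParams(1e9, 0.5, 0.5), exp1_table)
        assert np.allclose(local.probs, prior_pred.probs, atol=1e-6)

    def test_matches_two_hypothesis_bruteforce(self, exp1_table,
                                               learning_event):
        """Generic (alpha, beta): explicit enumeration over {same, new} x
        laws x outcomes reproduces the analytic path."""
        sp = exp1_table.space
        params = DPParams(0.7, 0.4, 0.5)
        task = cg.GeneralizationTask(sp.stone(color="blue", shape="circle"),
                                     sp.stone(color="red", shape="diamond"),
                                     sp.all_stones())
        # membership weights
        mu = category_mean([learning_event], params.beta, params.gamma, sp)
        w_same = (1 / (1 + params.alpha)) * mu.pair_likelihood(task.agent,
                                                               task.recipient)
        w_new = (params.alpha / (1 + params.alpha)) * uniform_pair_likelihood(sp)
        q = w_same / (w_same + w_new)
        # brute force over laws and outcomes for both hypotheses
        post_w = np.array([
            p * event_likelihood(learning_event, l, sp)
            for l, p in zip(exp1_table.laws, exp1_table.priors)])
        post_w /= post_w.sum()
        expected = np.zeros(9)
        for weights, comp in ((post_w, q), (exp1_table.priors, 1 - q)):
            vec = np.zeros(9)
            for l, w in zip(exp1_table.laws, weights):
                dom = l.outcomes(task.agent, task.recipient, sp)
                for idx, cand in enumerate(task.candidates):
                    if cand in dom:
                        vec[idx] += w / len(dom)
            expected += comp * vec / vec.sum()
        got = cg.locala_single_example(learning_event, task, params,
                                       exp1_table)
        assert np.allclose(got.probs, expected)

    def test_gamma_one_membership_ignores_recipient(self, learning_event):
        sp = cg.exp1_space()
        params = DPParams(1.0, 0.5, 1.0)
        agent = sp.stone(color="blue", shape="circle")
        panel = sp.all_stones()
        qs = {
            cg.single_example_membership(
                learning_event,
                cg.GeneralizationTask(agent, r, panel), params, sp)
            for r in panel
        }
        assert len(qs) == 1


class TestGibbs:
    def test_two_event_posterior_matches_enumeration(self, exp1_table):
        sp = exp1_table.space
        e1 = cg.CausalEvent(sp.stone(color="blue", shape="square"),
                            sp.stone(color="red", shape="diamond"),
                            sp.stone(color="blue", shape="diamond"))
        e2 = cg.CausalEvent(sp.stone(color="yellow", shape="circle"),
                            sp.stone(color="red", shape="square"),
                            sp.stone(color="yellow", shape="square"))
        params = DPParams(1.5, 0.5, 1.0)
        L = np.array([[event_likelihood(e, l, sp) for l in exp1_table.laws]
                      for e in (e1, e2)])
        m1, m2 = L @ exp1_table.priors
        m12 = exp1_table.priors @ (L[0] * L[1])
        mu1 = category_mean([e1], params.beta, params.gamma, sp)
        w_tog = (1 / (1 + params.alpha)) * mu1.pair_likelihood(e2.agent,
                                                               e2.recipient) * m12
        w_apart = (params.alpha / (1 + params.alpha)) \
            * uniform_pair_likelihood(sp) * m1 * m2
        exact = w_tog / (w_tog + w_apart)
        state = cg.gibbs_locala([e1, e2], params, exp1_table,
                                n_iter=12_000, burn_in=2_000, seed=3)
        assert abs(state.co_assignment(0, 1) - exact) < 0.02

    def test_small_alpha_merges_everything(self, exp2_table):
        design = cg.exp2_design("B1", seed=0)
        state = cg.gibbs_locala(design.learning_events,
                                DPParams(1e-8, 0.5, 1.0), exp2_table,
                                n_iter=200, seed=1)
        singles = sum(len(p.categories) == 1 for p in state.samples)
        assert singles / len(state.samples) > 0.99

    def test_fixed_agent_modal_single_category(self, exp2_table):
        """Six rule-consistent fixed-agent events with agent-only focus:
        the modal partition is one category whose law explains all six."""
        design = cg.exp2_design("B1", seed=0)
        state = cg.gibbs_locala(design.learning_events,
                                DPParams(5.0, 0.5, 1.0), exp2_table,
                                n_iter=500, seed=2)
        singles = [p for p in state.samples if len(p.categories) == 1]
        assert len(singles) > len(state.samples) / 2
        law = exp2_table.laws[singles[0].categories[0].law_index]
        for ev in design.learning_events:
            assert event_likelihood(ev, law, exp2_table.space) > 0

    def test_partition_relabeling_consistency(self, exp1_table):
        """Stored partitions are canonically labeled, so category ids never
        leak sampler internals."""
        sp = exp1_table.space
        events = [
            cg.CausalEvent(sp.stone(color="blue", shape="square"),
                           sp.stone(color="red", shape="circle"),
                           sp.stone(color="blue", shape="circle")),
            cg.CausalEvent(sp.stone(color="yellow", shape="diamond"),
                           sp.stone(color="red", shape="circle"),
                           sp.stone(color="red", shape="circle")),
        ]
        state = cg.gibbs_locala(events, DPParams(2.0, 0.5, 1.0), exp1_table,
                                n_iter=200, seed=0)
        for part in state.samples:
            firsts = [min(c.members) for c in part.categories]
            assert firsts == sorted(firsts)
            assert part.assignments[0] == 0

    def test_single_event_reduces_to_analytic(self, exp1_table,
                                              learning_event):
        sp = exp1_table.space
        params = DPParams(0.8, 0.3, 0.5)
        state = cg.gibbs_locala([learning_event], params, exp1_table,
                                n_iter=3000, seed=2)
        task = cg.GeneralizationTask(sp.stone(color="red", shape="square"),
                                     sp.stone(color="yellow", shape="circle"),
                                     sp.all_stones())
        exact = cg.locala_single_example(learning_event, task, params,
                                         exp1_table)
        approx = cg.locala_predict(state, task)
        assert 0.5 * np.abs(exact.probs - approx.probs).sum() < 0.02

    def test_n_iter_must_exceed_burn_in(self, exp1_table, learning_event):
        with pytest.raises(ValueError):
            cg.gibbs_locala([learning_event], DPParams(1.0), exp1_table,
                            n_iter=10, burn_in=10)


class TestLocalaPro:
    def test_seeded_determinism(self, exp1_table, a1_design):
        params = DPParams(0.38, 1.0, 0.5)
        d1, p1 = cg.localapro_run(a1_design, params, exp1_table, seed=5)
        d2, p2 = cg.localapro_run(a1_design, params, exp1_table, seed=5)
        assert p1 == p2
        assert all(np.array_equal(x.probs, y.probs) for x, y in zip(d1, d2))

    def test_small_alpha_tracks_posterior_predictive(self, exp1_table,
                                                     a1_design):
        params = DPParams(1e-6, 0.5, 0.5)
        post = cg.posterior_over_laws(exp1_table, a1_design.learning_events)
        preds = cg.localapro_predict(a1_design, params, exp1_table,
                                     n_runs=400, seed=0)
        for task, got in zip(a1_design.tasks, preds):
            want = cg.uncala_predict(post, task)
            assert 0.5 * np.abs(got.probs - want.probs).sum() < 0.05

    def test_large_alpha_approaches_prior(self, exp1_table, a1_design):
        params = DPParams(1e6, 0.5, 0.5)
        preds = cg.localapro_predict(a1_design, params, exp1_table,
                                     n_runs=3000, seed=0)
        for task, got in zip(a1_design.tasks, preds):
            want = mixture_choice_distribution(exp1_table.priors, exp1_table,
                                               task)
            assert 0.5 * np.abs(got.probs - want.probs).sum() < 0.05

    def test_commitment_grows_partition(self, exp1_table, a1_design):
        params = DPParams(0.38, 1.0, 0.5)
        _, part = cg.localapro_run(a1_design, params, exp1_table, seed=1)
        # one learning event + 15 committed tasks
        assert len(part.assignments) == 16
        assert sum(len(c.members) for c in part.categories) == 16


class TestDiagnosticsAndDumps:
    def test_sample_dump_round_trips_as_jsonl(self, exp1_table, tmp_path,
                                              learning_event):
        state = cg.gibbs_locala([learning_event], DPParams(1.0, 0.5, 1.0),
                                exp1_table, n_iter=50, seed=0)
        path = tmp_path / "samples.jsonl"
        cg.dump_samples(state, path)
        import json
        lines = [json.loads(l) for l in path.read_text().splitlines()]
        assert len(lines) == len(state.samples)
        first = lines[0]
        assert first["iteration"] == state.burn_in
        assert len(first["assignments"]) == 1
        # law strings parse back into the table's semantics
        for s in first["laws"]:
            exp1_table.index(cg.parse_law(s, exp1_table.space))

    def test_rhat_near_one_for_well_mixed_chains(self, exp1_table,
                                                 learning_event):
        sp = exp1_table.space
        e2 = cg.CausalEvent(sp.stone(color="yellow", shape="circle"),
                            sp.stone(color="red", shape="square"),
                            sp.stone(color="yellow", shape="square"))
        rhat = cg.gibbs_rhat([learning_event, e2], DPParams(1.5, 0.5, 1.0),
                             exp1_table, n_chains=3, n_iter=300, seed=1)
        assert 0.9 < rhat < 1.1
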