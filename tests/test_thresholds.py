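import math

import numpy as np
import pytest

import nmathresh as nt
from nmathresh import (
    DecisionRule,
    PosteriorSummary,
    PriorSpec,
    SolutionSet,
    common_bias_solution_set,
    optimal_treatment,
    refit_optimum,
    run_study_level,
    solution_set,
    thresholds_from_solutions,
)

from conftest import make_network, network_with_three_arm


class TestOptimalTreatment:
    def test_argmax_higher_better(self):
        post = PosteriorSummary(mean_d=[0.2, 0.9, -0.3], cov=np.eye(3))
        k, tied = optimal_treatment(post, DecisionRule("higher_better"))
        assert (k, tied) == (3, False)

    def test_argmin_lower_better(self):
        post = PosteriorSummary(mean_d=[0.2, 0.9, -0.3], cov=np.eye(3))
        k, tied = optimal_treatment(post, DecisionRule("lower_better"))
        assert (k, tied) == (4, False)

    def test_all_zero_means_reference_wins_with_tie_flag(self):
        post = PosteriorSummary(mean_d=[0.0, 0.0], cov=np.eye(2))
        k, tied = optimal_treatment(post)
        assert (k, tied) == (1, True)


class TestSolutionSet:
    def test_k2_single_datum_shift_to_tie(self, two_treatment_single_datum):
        # flat prior: E(d_2) = y_1, influence 1, so u_1 = -y_1
        post = nt.fit_fe(two_treatment_single_datum, PriorSpec.flat(2))
        h = nt.influence_fe(post, two_treatment_single_datum)
        kstar, _ = optimal_treatment(post)
        assert kstar == 2
        ss = solution_set(post, h, kstar, 0)
        assert ss.u[1] == pytest.approx(-0.5)

    def test_mcid_moves_solutions_away_from_zero(self, mixed_network):
        post = nt.fit_fe(mixed_network, PriorSpec.vague(4))
        h = nt.influence_fe(post, mixed_network)
        kstar, _ = optimal_treatment(post)
        prev = None
        for rho in [0.0, 0.1, 0.3, 0.6]:
            ss = solution_set(post, h, kstar, 1, DecisionRule(mcid=rho))
            mags = {a: abs(u) for a, u in ss.u.items() if math.isfinite(u)}
            if prev is not None:
                assert all(mags[a] >= prev[a] - 1e-12 for a in mags)
            prev = mags

    @pytest.mark.parametrize("seed", range(4))
    def test_contrast_changes_sign_at_solution(self, seed):
        net = make_network(seed=seed + 60, K=4)
        prior = PriorSpec.vague(4)
        post = nt.fit_fe(net, prior)
        h = nt.influence_fe(post, net)
        kstar, _ = optimal_treatment(post)
        full = post.mean_with_reference()
        m = seed % net.N
        ss = solution_set(post, h, kstar, m)
        for a, u in ss.u.items():
            if not math.isfinite(u):
                continue
            for eps, sgn in [(1e-6, 1.0), (-1e-6, -1.0)]:
                beta = np.zeros(net.N)
                beta[m] = u * (1 + eps * np.sign(u))
            # just beyond the solution, a's contrast with k* has flipped
            beta = np.zeros(net.N)
            beta[m] = u * (1 + 1e-6)
            post2 = nt.fit_fe(nt.adjust_data(net, beta), prior)
            full2 = post2.mean_with_reference()
            before = full[kstar - 1] - full[a - 1]
            after = full2[kstar - 1] - full2[a - 1]
            assert np.sign(after) != np.sign(before) or abs(after) < 1e-8

    def test_m_out_of_range(self, mixed_network):
        post = nt.fit_fe(mixed_network, PriorSpec.vague(4))
        h = nt.influence_fe(post, mixed_network)
        with pytest.raises(IndexError):
            solution_set(post, h, 1, mixed_network.N)


class TestThresholdsFromSolutions:
    def test_smallest_positive_and_largest_negative(self):
        ss = SolutionSet(m=0, kstar=2, u={1: -3.0, 3: 0.7, 4: -0.4, 5: 2.0})
        res = thresholds_from_solutions(ss)
        assert res.beta_pos == pytest.approx(0.7)
        assert res.new_opt_pos == 3
        assert res.beta_neg == pytest.approx(-0.4)
        assert res.new_opt_neg == 4

    def test_open_side_is_nt(self):
        ss = SolutionSet(m=0, kstar=2, u={1: math.inf, 3: -1.0})
        res = thresholds_from_solutions(ss)
        assert math.isinf(res.beta_pos)
        assert res.new_opt_pos is None

    def test_zero_solution_warns_degenerate(self):
        ss = SolutionSet(m=0, kstar=2, u={1: 0.0, 3: -1.0})
        with pytest.warns(UserWarning, match="degenerate"):
            res = thresholds_from_solutions(ss)
        assert res.beta_pos == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_lemma1_new_optimum_matches_refit(self, seed):
        net = make_network(seed=seed + 80, K=5, n_studies=9)
        prior = PriorSpec.vague(5)
        rule = DecisionRule()
        post = nt.fit_fe(net, prior)
        h = nt.influence_fe(post, net)
        kstar, _ = optimal_treatment(post, rule)
        for m in range(net.N):
            res = thresholds_from_solutions(solution_set(post, h, kstar, m, rule))
            for thresh, opt in [(res.beta_pos, res.new_opt_pos),
                                (res.beta_neg, res.new_opt_neg)]:
                if not math.isfinite(thresh):
                    continue
                beta = np.zeros(net.N)
                beta[m] = thresh * (1 + 1e-7) + np.sign(thresh) * 1e-12
                assert refit_optimum(net, beta, prior, "fe", rule) == opt


class TestCommonBias:
    def test_singleton_equals_single_datum(self, mixed_network):
        post = nt.fit_fe(mixed_network, PriorSpec.vague(4))
        h = nt.influence_fe(post, mixed_network)
        kstar, _ = optimal_treatment(post)
        single = solution_set(post, h, kstar, 2)
        combo = common_bias_solution_set(post, h, kstar, [2])
        assert combo.u == pytest.approx(single.u)

    def test_k2_all_data_flat_prior_closed_form(self, two_treatment_two_data):
        # weights sum to one, so a shared shift u moves E(d_2) by exactly u
        post = nt.fit_fe(two_treatment_two_data, PriorSpec.flat(2))
        h = nt.influence_fe(post, two_treatment_two_data)
        kstar, _ = optimal_treatment(post)
        combo = common_bias_solution_set(post, h, kstar, [0, 1])
        assert combo.u[1] == pytest.approx(-post.mean_d[0])

    def test_harmonic_identity(self, mixed_network):
        post = nt.fit_fe(mixed_network, PriorSpec.vague(4))
        h = nt.influence_fe(post, mixed_network)
        kstar, _ = optimal_treatment(post)
        ms = [0, 2, 3]
        singles = [solution_set(post, h, kstar, m) for m in ms]
        combo = common_bias_solution_set(post, h, kstar, ms)
        for a in combo.u:
            inv = sum(0.0 if math.isinf(s.u[a]) else 1.0 / s.u[a] for s in singles)
            expect = math.inf if inv == 0 else 1.0 / inv
            if math.isinf(expect):
                assert math.isinf(combo.u[a])
            else:
                assert combo.u[a] == pytest.approx(expect)

    def test_empty_set_rejected(self, mixed_network):
        post = nt.fit_fe(mixed_network, PriorSpec.vague(4))
        h = nt.influence_fe(post, mixed_network)
        with pytest.raises(ValueError, match="non-empty"):
            common_bias_solution_set(post, h, 1, [])


class TestRunStudyLevel:
    def test_one_result_per_datum_with_flags(self, mixed_network):
        results = run_study_level(mixed_network, PriorSpec.vague(4))
        assert len(results) == mixed_network.N
        for r, y_m in zip(results, mixed_network.y):
            assert r.estimate == pytest.approx(y_m)
            lo, hi = r.invariant_interval
            assert lo <= y_m <= hi
            assert isinstance(r.sensitive, bool)

    def test_sorted_smallest_threshold_first(self):
        net = make_network(seed=17, K=4)
        results = run_study_level(net, PriorSpec.vague(4), sort=True)
        keys = [r.smallest_threshold for r in results]
        assert keys == sorted(keys)

    def test_interval_validity_random_probes(self):
        net = make_network(seed=23, K=4)
        prior = PriorSpec.vague(4)
        rule = DecisionRule()
        results = run_study_level(net, prior, rule=rule)
        post = nt.fit_fe(net, prior)
        kstar, _ = optimal_treatment(post, rule)
        rng = np.random.default_rng(23)
        for m, r in enumerate(results):
            lo = max(r.beta_neg, -50.0)
            hi = min(r.beta_pos, 50.0)
            for b in rng.uniform(lo * 0.999, hi * 0.999, size=3):
                beta = np.zeros(net.N)
                beta[m] = b
                assert refit_optimum(net, beta, prior, "fe", rule) == kstar

    def test_scaling_equivariance(self):
        net = make_network(seed=31, K=4)
        c = 3.7
        scaled = nt.NetworkData(
            studies=[
                nt.Study(id=s.id, treatments=list(s.treatments),
                         y=c * s.y, V=c**2 * s.V)
                for s in net.studies
            ],
            n_treatments=4,
        )
        rule = DecisionRule(mcid=0.1)
        rule_scaled = DecisionRule(mcid=0.1 * c)
        res = run_study_level(net, PriorSpec.flat(4), rule=rule)
        res_scaled = run_study_level(scaled, PriorSpec.flat(4), rule=rule_scaled)
        for r, rs in zip(res, res_scaled):
            for attr in ("beta_neg", "beta_pos"):
                v, vs = getattr(r, attr), getattr(rs, attr)
                if math.isfinite(v):
                    assert vs == pytest.approx(c * v, rel=1e-8)
                else:
                    assert not math.isfinite(vs)

    def test_mcid_zero_reduces_to_plain_analysis(self, mixed_network):
        plain = run_study_level(mixed_network, PriorSpec.vague(4),
                                rule=DecisionRule())
        rho0 = run_study_level(mixed_network, PriorSpec.vague(4),
                               rule=DecisionRule(mcid=0.0))
        for a, b in zip(plain, rho0):
            assert a.beta_neg == b.beta_neg
            assert a.beta_pos == b.beta_pos
            assert a.new_opt_neg == b.new_opt_neg
            assert a.new_opt_pos == b.new_opt_pos

    def test_lower_better_mirrors_negated_network(self):
        net = make_network(seed=41, K=4)
        negated = nt.NetworkData(
            studies=[
                nt.Study(id=s.id, treatments=list(s.treatments),
                         y=-s.y, V=s.V.copy())
                for s in net.studies
            ],
            n_treatments=4,
            outcome_direction="lower_better",
        )
        res_hi = run_study_level(net, PriorSpec.vague(4),
                                 rule=DecisionRule("higher_better"))
        res_lo = run_study_level(negated, PriorSpec.vague(4),
                                 rule=DecisionRule("lower_better"))
        for rh, rl in zip(res_hi, res_lo):
            # adjustment thresholds flip sign with the data
            assert rl.beta_pos == pytest.approx(-rh.beta_neg)
            assert rl.beta_neg == pytest.approx(-rh.beta_pos)
            assert rl.new_opt_pos == rh.new_opt_neg
            assert rl.new_opt_neg == rh.new_opt_pos
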