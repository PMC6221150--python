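import numpy as np
import pytest

import nmathresh as nt
from nmathresh import (
    ClassSpec,
    ExtendedModelSpec,
    PriorSpec,
    adjust_data,
    influence_fe,
    influence_fe_extended,
    influence_frequentist,
    influence_re,
    influence_re_extended,
)
from nmathresh.network import build_design_matrix

from conftest import make_network, network_with_three_arm


def refit_delta(network, beta, fit):
    """Change in E(d) when the data move from y to y + beta."""
    return fit(adjust_data(network, beta)).mean_d - fit(network).mean_d


class TestInfluenceFE:
    def test_single_datum_flat_prior_is_one(self, two_treatment_single_datum):
        post = nt.fit_fe(two_treatment_single_datum, PriorSpec.flat(2))
        h = influence_fe(post, two_treatment_single_datum).H
        assert h == pytest.approx(np.array([[1.0]]))

    def test_two_data_weights_sum_to_one(self, two_treatment_two_data):
        post = nt.fit_fe(two_treatment_two_data, PriorSpec.flat(2))
        h = influence_fe(post, two_treatment_two_data).H
        w = np.array([1 / 0.1, 1 / 0.3])
        assert h == pytest.approx((w / w.sum())[None, :])
        assert h.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_refit_identity(self, seed):
        net = make_network(seed=seed, K=4, n_studies=8)
        prior = PriorSpec.vague(4)
        post = nt.fit_fe(net, prior)
        h = influence_fe(post, net).H
        rng = np.random.default_rng(seed)
        beta = rng.normal(0, 2.0, size=net.N)
        delta = refit_delta(net, beta, lambda n: nt.fit_fe(n, prior))
        assert delta == pytest.approx(h @ beta, rel=1e-8, abs=1e-10)

    def test_source_mismatch_rejected(self):
        net = make_network(seed=0)
        post = nt.fit_re_fixed_tau(net, PriorSpec.vague(4), 0.1)
        with pytest.raises(ValueError, match="source"):
            influence_fe(post, net)


class TestInfluenceRE:
    def test_tau2_zero_limit_equals_fe(self, mixed_network):
        prior = PriorSpec.vague(4)
        fe = influence_fe(nt.fit_fe(mixed_network, prior), mixed_network).H
        re0 = influence_re(
            nt.fit_re_fixed_tau(mixed_network, prior, 0.0), mixed_network
        ).H
        re_small = influence_re(
            nt.fit_re_fixed_tau(mixed_network, prior, 1e-8), mixed_network
        ).H
        assert re0 == pytest.approx(fe)
        assert re_small == pytest.approx(fe, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_refit_identity(self, seed):
        net = network_with_three_arm(seed=seed + 40, K=4)
        prior = PriorSpec.vague(4)
        tau2 = 0.25
        post = nt.fit_re_fixed_tau(net, prior, tau2)
        h = influence_re(post, net).H
        rng = np.random.default_rng(seed)
        beta = rng.normal(0, 2.0, size=net.N)
        delta = refit_delta(net, beta,
                            lambda n: nt.fit_re_fixed_tau(n, prior, tau2))
        assert delta == pytest.approx(h @ beta, rel=1e-8, abs=1e-10)

    def test_three_treatment_hand_algebra(self):
        # two independent two-arm studies (2 vs 1, 3 vs 1), flat prior:
        # marginally y_i ~ N(d_i, v_i + tau2), so H = diag(v_i/(v_i+tau2))
        # mapping is identity-weighted: dE(d_i)/dy_i = (1/(v_i+tau2))/(1/(v_i+tau2)) = 1
        from nmathresh import NetworkData, Study

        v1, v2, tau2 = 0.2, 0.5, 0.3
        net = NetworkData(studies=[
            Study(id="1", treatments=[1, 2], y=[0.4], V=[[v1]]),
            Study(id="2", treatments=[1, 3], y=[-0.2], V=[[v2]]),
        ])
        post = nt.fit_re_fixed_tau(net, PriorSpec.flat(3), tau2)
        h = influence_re(post, net).H
        # single datum per basic parameter: full weight on its own datum
        assert h == pytest.approx(np.eye(2), abs=1e-10)

    def test_missing_b_star_rejected(self, mixed_network):
        post = nt.fit_fe(mixed_network, PriorSpec.vague(4))
        with pytest.raises(ValueError, match="B_star"):
            influence_re(post, mixed_network)


class TestInfluenceExtended:
    def test_no_extras_equals_fe(self, mixed_network):
        prior = PriorSpec.vague(4)
        fe = influence_fe(nt.fit_fe(mixed_network, prior), mixed_network).H
        post = nt.fit_fe_extended(mixed_network, prior, ExtendedModelSpec())
        h = influence_fe_extended(post, mixed_network, ExtendedModelSpec()).H
        assert h == pytest.approx(fe)

    def test_fe_extended_refit_oracle(self, mixed_network):
        # nuisance covariate column in the likelihood (e.g. a shared offset)
        rng = np.random.default_rng(3)
        m = rng.normal(size=(mixed_network.N, 2))
        ext = ExtendedModelSpec(M=m, mu0=np.zeros(2), Sigma_mu=4.0 * np.eye(2))
        prior = PriorSpec.vague(4)
        post = nt.fit_fe_extended(mixed_network, prior, ext)
        h = influence_fe_extended(post, mixed_network, ext)
        assert h.H.shape == (3, mixed_network.N)
        beta = rng.normal(0, 1.5, size=mixed_network.N)
        delta = refit_delta(mixed_network, beta,
                            lambda n: nt.fit_fe_extended(n, prior, ext))
        assert delta == pytest.approx(h.H @ beta, rel=1e-8, abs=1e-10)

    def test_re_extended_reduces_to_re(self, mixed_network):
        prior = PriorSpec.vague(4)
        post = nt.fit_re_extended(mixed_network, prior, 0.3, ExtendedModelSpec())
        h = influence_re_extended(post, mixed_network, ExtendedModelSpec()).H
        base = influence_re(
            nt.fit_re_fixed_tau(mixed_network, prior, 0.3), mixed_network
        ).H
        assert h == pytest.approx(base)

    def test_re_extended_refit_oracle(self, mixed_network):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(mixed_network.N, 1))
        ext = ExtendedModelSpec(M=m, mu0=np.zeros(1), Sigma_mu=np.eye(1))
        prior = PriorSpec.vague(4)
        post = nt.fit_re_extended(mixed_network, prior, 0.2, ext)
        h = influence_re_extended(post, mixed_network, ext)
        beta = rng.normal(0, 1.0, size=mixed_network.N)
        delta = refit_delta(mixed_network, beta,
                            lambda n: nt.fit_re_extended(n, prior, 0.2, ext))
        assert delta == pytest.approx(h.H @ beta, rel=1e-8, abs=1e-10)

    @pytest.mark.parametrize("sigma_class", [0.0, 0.15])
    def test_class_effect_refit_oracle(self, mixed_network, sigma_class):
        z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        spec = ClassSpec(Z=z, Sigma_class=sigma_class * np.eye(3),
                         z0=np.zeros(2), Sigma_z=10.0 * np.eye(2))
        fit = lambda n: nt.fit_class_re(n, spec, tau2=0.2)
        post = fit(mixed_network)
        ext = ExtendedModelSpec(M=np.zeros((mixed_network.N, 2)))
        h = influence_re_extended(post, mixed_network, ext)
        assert h.H.shape == (3, mixed_network.N)
        rng = np.random.default_rng(11)
        beta = rng.normal(0, 1.0, size=mixed_network.N)
        delta = refit_delta(mixed_network, beta, fit)
        assert delta == pytest.approx(h.H @ beta, rel=1e-8, abs=1e-10)


class TestInfluenceFrequentist:
    def test_equals_flat_prior_fe(self, mixed_network):
        post = nt.fit_fe(mixed_network, PriorSpec.flat(4))
        fe = influence_fe(post, mixed_network).H
        freq = influence_frequentist(mixed_network).H
        assert freq == pytest.approx(fe)

    def test_hat_matrix_idempotent(self, mixed_network):
        x = build_design_matrix(mixed_network)
        h = influence_frequentist(mixed_network).H
        hat = x @ h
        assert hat @ hat == pytest.approx(hat, abs=1e-10)

    def test_k2_weights(self, two_treatment_two_data):
        h = influence_frequentist(two_treatment_two_data).H
        w = np.array([1 / 0.1, 1 / 0.3])
        assert h == pytest.approx((w / w.sum())[None, :])


class TestPermutation:
    def test_columns_permute_with_study_order(self, mixed_network):
        from nmathresh import NetworkData

        prior = PriorSpec.vague(4)
        h = influence_fe(nt.fit_fe(mixed_network, prior), mixed_network).H
        # reverse the study order
        perm_net = NetworkData(
            studies=list(reversed(mixed_network.studies)),
            n_treatments=4,
        )
        h2 = influence_fe(nt.fit_fe(perm_net, prior), perm_net).H
        # map datum positions of perm_net back to original positions
        labels = mixed_network.datum_labels
        labels2 = perm_net.datum_labels
        order = [labels2.index(lab) for lab in labels]
        assert h2[:, order] == pytest.approx(h)
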