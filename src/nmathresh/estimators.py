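"""Estimator-style front end to the NMA fits and threshold analyses.

These classes follow the scikit-learn protocol (``fit`` plus trailing-
underscore fitted attributes, ``get_params``/``set_params``) so they slot
into generic tooling; the closed-form algebra itself lives in the
functional modules (:mod:`~nmathresh.posterior`, :mod:`~nmathresh.influence`,
:mod:`~nmathresh.thresholds`, :mod:`~nmathresh.contrast_level`), which the
estimators delegate to.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import contrast_level as _cl
from . import influence as _infl
from . import posterior as _post
from . import thresholds as _thr
from .network import NetworkData, PriorSpec

__all__ = [
    "FixedEffectNMA",
    "RandomEffectsNMA",
    "StudyLevelThresholds",
    "ContrastLevelThresholds",
]


class _NMABase(BaseEstimator):
    def _resolve_prior(self, network: NetworkData) -> PriorSpec | None:
        if self.prior == "vague" or self.prior is None:
            return PriorSpec.vague(network.K)
        if self.prior == "flat":
            return PriorSpec.flat(network.K)
        return self.prior

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise AttributeError("estimator is not fitted; call fit(network) first")


class FixedEffectNMA(_NMABase):
    """Conjugate fixed-effect NMA.

    Parameters
    ----------
    prior : 'vague', 'flat' or PriorSpec
        Prior on the basic effects; 'vague' is N(0, 1e6 I), 'flat' the
        improper flat prior giving the GLS fit.

    Attributes (after fit)
    ----------------------
    posterior_ : PosteriorSummary
    mean_d_, cov_ : posterior mean and covariance of d
    influence_ : (K-1) x N influence matrix H = Sigma_n X' V^-1
    """

    def __init__(self, prior="vague"):
        self.prior = prior

    def fit(self, network: NetworkData, y=None):
        if not isinstance(network, NetworkData):
            raise TypeError("fit expects a NetworkData instance")
        post = _post.fit_fe(network, self._resolve_prior(network))
        self.posterior_ = post
        self.mean_d_ = post.mean_d
        self.cov_ = post.cov
        self.influence_ = _infl.influence_fe(post, network).H
        self.network_ = network
        return self

    def predict(self, contrasts):
        """Posterior means of the requested (a, b) contrasts d_b - d_a."""
        self._check_fitted()
        return np.array(
            [_post.contrast_mean(self.posterior_, a, b) for a, b in contrasts]
        )


class RandomEffectsNMA(_NMABase):
    """Conjugate RE NMA with known, fixed between-study variance tau2.

    tau2 = 0 degenerates to the FE model.  Fitted attributes include the
    cov(d, delta) partition ``b_star_`` and the RE influence matrix
    H = B* V^-1.
    """

    def __init__(self, tau2=0.0, prior="vague"):
        self.tau2 = tau2
        self.prior = prior

    def fit(self, network: NetworkData, y=None):
        if not isinstance(network, NetworkData):
            raise TypeError("fit expects a NetworkData instance")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        post = _post.fit_re_fixed_tau(network, self._resolve_prior(network), self.tau2)
        self.posterior_ = post
        self.mean_d_ = post.mean_d
        self.cov_ = post.cov
        self.b_star_ = post.B_star
        self.influence_ = _infl.influence_re(post, network).H
        self.network_ = network
        return self

    def predict(self, contrasts):
        self._check_fitted()
        return np.array(
            [_post.contrast_mean(self.posterior_, a, b) for a, b in contrasts]
        )


class StudyLevelThresholds(_NMABase):
    """Study-level bias-adjustment threshold analysis.

    Fits the chosen model and derives, for every data point, the invariant
    interval and new optima.  ``results_`` holds one ThresholdResult per
    datum; ``kstar_`` is the base-case optimal treatment.
    """

    def __init__(self, model="fe", tau2=None, prior="vague",
                 direction=None, mcid=0.0):
        self.model = model
        self.tau2 = tau2
        self.prior = prior
        self.direction = direction
        self.mcid = mcid

    def fit(self, network: NetworkData, y=None):
        if not isinstance(network, NetworkData):
            raise TypeError("fit expects a NetworkData instance")
        direction = self.direction or network.outcome_direction
        rule = _thr.DecisionRule(direction=direction, mcid=self.mcid)
        self.results_ = _thr.run_study_level(
            network,
            self._resolve_prior(network),
            model=self.model,
            rule=rule,
            tau2=self.tau2,
        )
        if self.model == "re":
            post = _post.fit_re_fixed_tau(
                network, self._resolve_prior(network), self.tau2
            )
        else:
            post = _post.fit_fe(network, self._resolve_prior(network))
        self.posterior_ = post
        self.kstar_, self.kstar_tied_ = _thr.optimal_treatment(post, rule)
        self.rule_ = rule
        self.network_ = network
        return self

    def transform(self, network: NetworkData = None):
        """Invariant intervals as an (N, 2) array."""
        self._check_fitted()
        return np.array([r.invariant_interval for r in self.results_])


class ContrastLevelThresholds(_NMABase):
    """Contrast-level threshold analysis from a posterior summary.

    Parameters name the contrasts with direct evidence; ``fit`` consumes a
    PosteriorSummary (or mean/cov via ``fit_mean_cov``).  Fitted attributes:
    ``results_`` (per-contrast thresholds), ``reconstruction_`` (the
    hypothetical likelihood), ``kl_`` and ``kl_verdict_``.
    """

    def __init__(self, direct_contrasts=None, prior="vague",
                 direction="higher_better", mcid=0.0):
        self.direct_contrasts = direct_contrasts
        self.prior = prior
        self.direction = direction
        self.mcid = mcid

    def fit(self, posterior: _post.PosteriorSummary, y=None):
        if self.direct_contrasts is None:
            raise ValueError("direct_contrasts must be provided")
        if not isinstance(posterior, _post.PosteriorSummary):
            raise TypeError("fit expects a PosteriorSummary")
        k = posterior.K
        prior = (
            PriorSpec.vague(k) if self.prior in ("vague", None)
            else PriorSpec.flat(k) if self.prior == "flat"
            else self.prior
        )
        rule = _thr.DecisionRule(direction=self.direction, mcid=self.mcid)
        self.results_, self.reconstruction_ = _cl.run_contrast_level(
            posterior, prior, self.direct_contrasts, rule
        )
        self.kl_ = self.reconstruction_.kl
        self.kl_, self.kl_verdict_ = _cl.kl_diagnostic(
            posterior.mean_d, posterior.cov,
            posterior.mean_d, self.reconstruction_.cov_hat,
        )
        self.kstar_, _ = _thr.optimal_treatment(posterior, rule)
        self.posterior_ = posterior
        return self

    def fit_mean_cov(self, mean, cov):
        return self.fit(_post.PosteriorSummary(mean_d=mean, cov=cov))
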