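"""Influence matrices: linear maps from data perturbations to posterior means.

For every model variant with a normal joint posterior, an additive change
beta to the data changes the posterior mean of the basic effects linearly,

    E(d | y + beta) = E(d | y) + H beta,

and all bias-adjustment thresholds are read off from H.  The form of the
(K-1) x N matrix H depends on the model:

=================  =======================================
fixed effect       H = Sigma_n X' V^-1
random effects     H = B* V^-1
FE + extra params  H = [Sigma_n X_ext' V^-1] rows 1..K-1
RE + extra params  H = (B* L' + D* M') V^-1
frequentist (GLS)  H = (X' V^-1 X)^-1 X' V^-1
=================  =======================================

The frequentist H coincides with the flat-prior Bayesian FE case, and X H is
then the hat matrix of the generalised least squares fit (idempotent),
familiar from "flow of evidence" displays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._linalg import spd_inv
from .network import NetworkData, build_design_matrix
from .posterior import ExtendedModelSpec, PosteriorSummary

__all__ = [
    "InfluenceMatrix",
    "influence_fe",
    "influence_re",
    "influence_fe_extended",
    "influence_re_extended",
    "influence_frequentist",
    "influence_contrast_level",
]

_VARIANTS = (
    "fe", "re", "fe_extended", "re_extended", "class_re",
    "contrast_level", "frequentist",
)


@dataclass
class InfluenceMatrix:
    H: np.ndarray
    model_variant: str

    def __post_init__(self) -> None:
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        if self.model_variant not in _VARIANTS:
            raise ValueError(f"unknown model variant {self.model_variant!r}")
        if not np.all(np.isfinite(self.H)):
            raise ValueError("influence matrix has non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.H.shape

    def to_frame(self, network: NetworkData | None = None) -> pd.DataFrame:
        """Labelled H: treatment rows 2..K, datum columns."""
        rows = [f"d[{k}]" for k in range(2, self.H.shape[0] + 2)]
        cols = (network.datum_labels if network is not None
                else [f"y[{m + 1}]" for m in range(self.H.shape[1])])
        return pd.DataFrame(self.H, index=rows, columns=cols)


def _check_source(posterior: PosteriorSummary, allowed: tuple[str, ...], op: str):
    if posterior.source not in allowed:
        raise ValueError(
            f"{op}: posterior source {posterior.source!r} not in {allowed}"
        )


def influence_fe(
    posterior: PosteriorSummary, network: NetworkData
) -> InfluenceMatrix:
    """H = Sigma_n X' V^-1 for the conjugate FE model."""
    _check_source(posterior, ("fitted_fe", "external"), "influence_fe")
    x = build_design_matrix(network)
    return InfluenceMatrix(
        H=posterior.cov @ x.T @ spd_inv(network.V, "V"), model_variant="fe"
    )


def influence_re(
    posterior: PosteriorSummary, network: NetworkData
) -> InfluenceMatrix:
    """H = B* V^-1 for the fixed-tau^2 RE model."""
    if posterior.B_star is None:
        raise ValueError("influence_re: posterior carries no B_star partition")
    return InfluenceMatrix(
        H=posterior.B_star @ spd_inv(network.V, "V"), model_variant="re"
    )


def influence_fe_extended(
    posterior: PosteriorSummary,
    network: NetworkData,
    extended: ExtendedModelSpec | None = None,
) -> InfluenceMatrix:
    """Top K-1 rows of Sigma_n X_ext' V^-1 for the extended FE model."""
    if posterior.joint_cov is None:
        raise ValueError("influence_fe_extended: posterior carries no joint covariance")
    if extended is None:
        extended = ExtendedModelSpec()
    x = build_design_matrix(network)
    _, m, _, _ = extended.resolved(network.N)
    x_ext = np.hstack([x, m])
    k1 = x.shape[1]
    if posterior.joint_cov.shape[0] != x_ext.shape[1]:
        raise ValueError("extended design does not conform to the joint posterior")
    h_full = posterior.joint_cov @ x_ext.T @ spd_inv(network.V, "V")
    return InfluenceMatrix(H=h_full[:k1, :], model_variant="fe_extended")


def influence_re_extended(
    posterior: PosteriorSummary,
    network: NetworkData,
    extended: ExtendedModelSpec | None = None,
) -> InfluenceMatrix:
    """H = (B* L' + D* M') V^-1; also serves class-effect RE models."""
    if posterior.B_star is None or posterior.D_star is None:
        raise ValueError(
            "influence_re_extended: posterior must carry B_star and D_star"
        )
    if extended is None:
        extended = ExtendedModelSpec()
    l, m, _, _ = extended.resolved(network.N)
    variant = "class_re" if posterior.source == "fitted_class_re" else "re_extended"
    h = (posterior.B_star @ l.T + posterior.D_star @ m.T) @ spd_inv(network.V, "V")
    return InfluenceMatrix(H=h, model_variant=variant)


def influence_frequentist(network: NetworkData) -> InfluenceMatrix:
    """GLS influence H = (X' V^-1 X)^-1 X' V^-1 (needs full-rank X)."""
    x = build_design_matrix(network)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient; network not connected")
    vi = spd_inv(network.V, "V")
    return InfluenceMatrix(
        H=spd_inv(x.T @ vi @ x, "X'V^-1X") @ x.T @ vi,
        model_variant="frequentist",
    )


def influence_contrast_level(
    cov: np.ndarray, x_c: np.ndarray, weights: np.ndarray
) -> InfluenceMatrix:
    """H = Sigma X_c' W for the reconstructed contrast-level likelihood.

    ``weights`` are the precisions 1/v_ab of the hypothetical contrast data
    (0 where the reconstructed variance is infinite, so such contrasts have
    no influence).
    """
    h = cov @ x_c.T @ np.diag(np.asarray(weights, dtype=float))
    return InfluenceMatrix(H=h, model_variant="contrast_level")


def dump_influence(
    influence: InfluenceMatrix, path, network: NetworkData | None = None
) -> None:
    influence.to_frame(network).to_csv(path)
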