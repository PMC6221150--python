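"""Closed-form conjugate posteriors for normal-likelihood NMA models.

With a multivariate normal likelihood y | delta ~ N(delta, V), linear model
structure and a normal prior on the basic effects d, the joint posterior of
all parameters is multivariate normal and available in closed form.  The
fixed-effect (FE) model has

    d | y ~ N( Sigma_n (Sigma_d^-1 d0 + X' V^-1 y), Sigma_n ),
    Sigma_n = (Sigma_d^-1 + X' V^-1 X)^-1,

while the random-effects (RE) model with *fixed, known* between-study
variance tau^2 yields a joint normal posterior over (d, delta) whose
covariance we partition to extract B* = cov(d, delta) — the ingredient of
the RE influence matrix.  Extended models stack nuisance parameters mu
(e.g. study baselines) or class effects z on top of the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linalg import spd_inv
from .network import NetworkData, PriorSpec, build_design_matrix, build_re_covariance

__all__ = [
    "PosteriorSummary",
    "ExtendedModelSpec",
    "ClassSpec",
    "fit_fe",
    "fit_re_fixed_tau",
    "fit_fe_extended",
    "fit_re_extended",
    "fit_class_re",
    "partition_external_posterior",
    "contrast_mean",
]


@dataclass
class PosteriorSummary:
    """Normal posterior of the K-1 basic effects, with optional partitions.

    ``B_star`` is cov(d, delta) for RE models and ``D_star`` is cov(d, mu)
    for extended models; both are slices of the joint posterior covariance.
    """

    mean_d: np.ndarray
    cov: np.ndarray
    source: str = "external"
    B_star: np.ndarray | None = None
    D_star: np.ndarray | None = None
    joint_mean: np.ndarray | None = None
    joint_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean_d = np.atleast_1d(np.asarray(self.mean_d, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        k1 = self.mean_d.shape[0]
        if self.cov.shape != (k1, k1):
            raise ValueError("cov shape does not match mean_d")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8 * max(1.0, np.abs(self.cov).max())):
            raise ValueError("cov must be symmetric")

    @property
    def K(self) -> int:
        """Number of treatments (reference included)."""
        return self.mean_d.shape[0] + 1

    def mean_with_reference(self) -> np.ndarray:
        """E(d_k) for k = 1..K with d_1 = 0 prepended."""
        return np.concatenate([[0.0], self.mean_d])


@dataclass
class ClassSpec:
    """Treatment-class structure: d | z ~ N(Z z, Sigma_class).

    ``Z`` is (K-1) x p assigning each non-reference treatment to a class;
    ``Sigma_class`` is the between-treatment (within-class) covariance — the
    zero matrix gives fixed class effects (d = Z z exactly).
    """

    Z: np.ndarray
    Sigma_class: np.ndarray
    z0: np.ndarray
    Sigma_z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.Sigma_class = np.atleast_2d(np.asarray(self.Sigma_class, dtype=float))
        self.z0 = np.atleast_1d(np.asarray(self.z0, dtype=float))
        self.Sigma_z = np.atleast_2d(np.asarray(self.Sigma_z, dtype=float))
        p = self.Z.shape[1]
        if self.z0.shape[0] != p or self.Sigma_z.shape != (p, p):
            raise ValueError("class prior dimensions disagree with Z")
        if self.Sigma_class.shape != (self.Z.shape[0], self.Z.shape[0]):
            raise ValueError("Sigma_class must be (K-1) x (K-1)")

    @property
    def fixed(self) -> bool:
        return not np.any(self.Sigma_class)


@dataclass
class ExtendedModelSpec:
    """Extra structure for models beyond the basic FE/RE.

    ``M`` (N x p) is the design of additional parameters mu in the likelihood
    (e.g. study-baseline nuisance parameters for arm-level data); ``L``
    (N x N_delta) links the study effects delta to the data (identity by
    default).  ``class_spec`` switches on the class-effect hierarchy.
    """

    M: np.ndarray | None = None
    L: np.ndarray | None = None
    mu0: np.ndarray | None = None
    Sigma_mu: np.ndarray | None = None
    class_spec: ClassSpec | None = None

    def resolved(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        l = np.eye(n) if self.L is None else np.atleast_2d(np.asarray(self.L, float))
        m = (np.zeros((n, 0)) if self.M is None
             else np.atleast_2d(np.asarray(self.M, float)))
        p = m.shape[1]
        mu0 = np.zeros(p) if self.mu0 is None else np.asarray(self.mu0, float)
        smu = (np.eye(p) * 1e6 if self.Sigma_mu is None
               else np.atleast_2d(np.asarray(self.Sigma_mu, float)))
        if l.shape[0] != n or m.shape[0] != n:
            raise ValueError("L and M must have one row per datum")
        if mu0.shape[0] != p or smu.shape != (p, p):
            raise ValueError("mu prior dimensions disagree with M")
        return l, m, mu0, smu


# ----------------------------------------------------------------------
# basic models
# ----------------------------------------------------------------------

def _design_and_data(network: NetworkData, prior: PriorSpec | None):
    x = build_design_matrix(network)
    if prior is None:
        prior = PriorSpec.vague(network.K)
    if prior.d0.shape[0] != network.K - 1:
        raise ValueError(
            f"prior dimension {prior.d0.shape[0]} != K-1 = {network.K - 1}"
        )
    return x, network.y, network.V, prior


def fit_fe(network: NetworkData, prior: PriorSpec | None = None) -> PosteriorSummary:
    """Conjugate fixed-effect fit.

    With an improper flat prior this reduces to generalised least squares,
    d_hat = (X' V^-1 X)^-1 X' V^-1 y.
    """
    x, y, v, prior = _design_and_data(network, prior)
    vi = spd_inv(v, "V")
    prec_prior = prior.precision()
    sigma_n = spd_inv(prec_prior + x.T @ vi @ x, "posterior precision")
    mean = sigma_n @ (prec_prior @ prior.d0 + x.T @ vi @ y)
    return PosteriorSummary(mean_d=mean, cov=sigma_n, source="fitted_fe")


def fit_re_fixed_tau(
    network: NetworkData, prior: PriorSpec | None = None, tau2: float = 0.0
) -> PosteriorSummary:
    """RE fit with known, fixed between-study variance tau^2.

    Builds the joint normal posterior over (d, delta) and extracts
    B* = cov(d, delta).  ``tau2 = 0`` falls back to the FE fit (delta = X d
    exactly; B* is then Sigma_n X' by continuity, which yields the FE
    influence matrix).
    """
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    x, y, v, prior = _design_and_data(network, prior)
    if tau2 == 0:
        post = fit_fe(network, prior)
        post.B_star = post.cov @ x.T
        post.source = "fitted_re"
        return post
    n, k1 = x.shape
    vi = spd_inv(v, "V")
    sti = spd_inv(build_re_covariance(network, tau2), "Sigma_tau2")
    prec = np.block(
        [
            [x.T @ sti @ x + prior.precision(), -x.T @ sti],
            [-sti @ x, vi + sti],
        ]
    )
    joint_cov = spd_inv(prec, "joint posterior precision")
    b = np.concatenate([prior.precision() @ prior.d0, vi @ y])
    joint_mean = joint_cov @ b
    return PosteriorSummary(
        mean_d=joint_mean[:k1],
        cov=joint_cov[:k1, :k1],
        source="fitted_re",
        B_star=joint_cov[:k1, k1:],
        joint_mean=joint_mean,
        joint_cov=joint_cov,
    )


# ----------------------------------------------------------------------
# extended models
# ----------------------------------------------------------------------

def fit_fe_extended(
    network: NetworkData,
    prior: PriorSpec | None = None,
    extended: ExtendedModelSpec | None = None,
) -> PosteriorSummary:
    """FE model with additional parameters mu: y | d, mu ~ N(X d + M mu, V).

    The parameter vector is gamma = (d, mu) with extended design [X M]; the
    posterior over gamma is conjugate normal exactly as in the basic case.
    """
    x, y, v, prior = _design_and_data(network, prior)
    if extended is None:
        extended = ExtendedModelSpec()
    _, m, mu0, smu = extended.resolved(network.N)
    k1, p = x.shape[1], m.shape[1]
    x_ext = np.hstack([x, m])
    vi = spd_inv(v, "V")
    prec_prior = np.zeros((k1 + p, k1 + p))
    prec_prior[:k1, :k1] = prior.precision()
    prec_prior[k1:, k1:] = np.linalg.inv(smu) if p else smu
    sigma_n = spd_inv(prec_prior + x_ext.T @ vi @ x_ext, "posterior precision")
    b = prec_prior @ np.concatenate([prior.d0, mu0]) + x_ext.T @ vi @ y
    mean = sigma_n @ b
    return PosteriorSummary(
        mean_d=mean[:k1],
        cov=sigma_n[:k1, :k1],
        source="fitted_fe_extended",
        D_star=sigma_n[:k1, k1:],
        joint_mean=mean,
        joint_cov=sigma_n,
    )


def fit_re_extended(
    network: NetworkData,
    prior: PriorSpec | None = None,
    tau2: float = 0.0,
    extended: ExtendedModelSpec | None = None,
) -> PosteriorSummary:
    """RE model with extra parameters: y ~ N(L delta + M mu, V),
    delta | d ~ N(X d, Sigma_tau2), fixed tau^2.

    Returns the joint posterior over (d, delta, mu) with the B* = cov(d,
    delta) and D* = cov(d, mu) partitions needed for influence analysis.
    A class-effect hierarchy (``extended.class_spec``) replaces the prior on
    d by d | z ~ N(Z z, Sigma_class) with a normal prior on z.
    """
    if extended is None:
        extended = ExtendedModelSpec()
    if extended.class_spec is not None:
        return fit_class_re(network, extended.class_spec, tau2, prior,
                            extended=extended)
    if tau2 <= 0:
        raise ValueError("fit_re_extended requires tau2 > 0; use fit_fe_extended")
    x, y, v, prior = _design_and_data(network, prior)
    n = network.N
    l, m, mu0, smu = extended.resolved(n)
    k1, p = x.shape[1], m.shape[1]
    vi = spd_inv(v, "V")
    sti = spd_inv(build_re_covariance(network, tau2), "Sigma_tau2")
    smu_i = np.linalg.inv(smu) if p else smu
    nd = l.shape[1]
    prec = np.zeros((k1 + nd + p, k1 + nd + p))
    prec[:k1, :k1] = x.T @ sti @ x + prior.precision()
    prec[:k1, k1:k1 + nd] = -x.T @ sti
    prec[k1:k1 + nd, :k1] = -sti @ x
    prec[k1:k1 + nd, k1:k1 + nd] = l.T @ vi @ l + sti
    prec[k1:k1 + nd, k1 + nd:] = l.T @ vi @ m
    prec[k1 + nd:, k1:k1 + nd] = m.T @ vi @ l
    prec[k1 + nd:, k1 + nd:] = m.T @ vi @ m + smu_i
    joint_cov = spd_inv(prec, "joint posterior precision")
    b = np.concatenate(
        [prior.precision() @ prior.d0, l.T @ vi @ y, m.T @ vi @ y + smu_i @ mu0]
    )
    joint_mean = joint_cov @ b
    return PosteriorSummary(
        mean_d=joint_mean[:k1],
        cov=joint_cov[:k1, :k1],
        source="fitted_re_extended",
        B_star=joint_cov[:k1, k1:k1 + nd],
        D_star=joint_cov[:k1, k1 + nd:],
        joint_mean=joint_mean,
        joint_cov=joint_cov,
    )


def fit_class_re(
    network: NetworkData,
    class_spec: ClassSpec,
    tau2: float,
    prior: PriorSpec | None = None,  # unused; class hierarchy replaces it
    extended: ExtendedModelSpec | None = None,
) -> PosteriorSummary:
    """Class-effect RE model: d | z ~ N(Z z, Sigma_class), fixed tau^2.

    Exchangeable classes (Sigma_class positive definite) are fitted jointly
    over (d, delta, z); z plays the role of the extra parameters mu with an
    all-zero likelihood design M = 0, so the extended-RE influence formula
    applies unchanged.  Fixed class effects (Sigma_class = 0) impose
    d = Z z exactly and are fitted by reparametrising the design to X Z.
    """
    if tau2 <= 0:
        raise ValueError("fit_class_re requires tau2 > 0")
    x = build_design_matrix(network)
    y, v, n = network.y, network.V, network.N
    k1 = x.shape[1]
    p = class_spec.Z.shape[1]
    vi = spd_inv(v, "V")
    sti = spd_inv(build_re_covariance(network, tau2), "Sigma_tau2")
    sz_i = np.linalg.inv(class_spec.Sigma_z)
    z = class_spec.Z

    if class_spec.fixed:
        # d = Z z: fit the RE model in z with design X Z, then map back.
        xz = x @ z
        prec = np.block(
            [[xz.T @ sti @ xz + sz_i, -xz.T @ sti], [-sti @ xz, vi + sti]]
        )
        cov_zd = spd_inv(prec, "joint posterior precision")
        b = np.concatenate([sz_i @ class_spec.z0, vi @ y])
        mean_zd = cov_zd @ b
        mean_d = z @ mean_zd[:p]
        cov_d = z @ cov_zd[:p, :p] @ z.T
        b_star = z @ cov_zd[:p, p:]
        return PosteriorSummary(
            mean_d=mean_d, cov=cov_d, source="fitted_class_re",
            B_star=b_star, D_star=np.zeros((k1, p)),
        )

    sc_i = np.linalg.inv(class_spec.Sigma_class)
    # parameter order (d, delta, z); z has zero design in the likelihood
    prec = np.zeros((k1 + n + p, k1 + n + p))
    prec[:k1, :k1] = x.T @ sti @ x + sc_i
    prec[:k1, k1:k1 + n] = -x.T @ sti
    prec[k1:k1 + n, :k1] = -sti @ x
    prec[k1:k1 + n, k1:k1 + n] = vi + sti
    prec[:k1, k1 + n:] = -sc_i @ z
    prec[k1 + n:, :k1] = -z.T @ sc_i
    prec[k1 + n:, k1 + n:] = z.T @ sc_i @ z + sz_i
    joint_cov = spd_inv(prec, "joint posterior precision")
    b = np.concatenate([np.zeros(k1), vi @ y, sz_i @ class_spec.z0])
    joint_mean = joint_cov @ b
    return PosteriorSummary(
        mean_d=joint_mean[:k1],
        cov=joint_cov[:k1, :k1],
        source="fitted_class_re",
        B_star=joint_cov[:k1, k1:k1 + n],
        D_star=joint_cov[:k1, k1 + n:],
        joint_mean=joint_mean,
        joint_cov=joint_cov,
    )


# ----------------------------------------------------------------------
# external posteriors
# ----------------------------------------------------------------------

def partition_external_posterior(
    mean: np.ndarray,
    cov: np.ndarray | None = None,
    layout: dict[str, slice | np.ndarray] | None = None,
    draws: np.ndarray | None = None,
) -> PosteriorSummary:
    """Partition an externally supplied joint posterior.

    ``layout`` maps block names ``'d'``, ``'delta'``, ``'mu'`` to index
    arrays or slices into the joint mean/covariance; only ``'d'`` is
    required.  ``draws`` (n_samples x dim) may be given instead of
    ``mean``/``cov``, in which case empirical moments are used.
    """
    if draws is not None:
        draws = np.asarray(draws, dtype=float)
        mean = draws.mean(axis=0)
        cov = np.cov(draws, rowvar=False)
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if layout is None:
        layout = {"d": np.arange(mean.shape[0])}
    if "d" not in layout:
        raise ValueError("layout must name the 'd' block")

    def _idx(key):
        sel = layout[key]
        return np.arange(mean.shape[0])[sel] if isinstance(sel, slice) else np.asarray(sel)

    d_idx = _idx("d")
    if d_idx.size == 0 or d_idx.max() >= mean.shape[0]:
        raise ValueError("layout 'd' indices do not conform to the posterior")
    out = PosteriorSummary(
        mean_d=mean[d_idx], cov=cov[np.ix_(d_idx, d_idx)], source="external",
        joint_mean=mean, joint_cov=cov,
    )
    if "delta" in layout:
        out.B_star = cov[np.ix_(d_idx, _idx("delta"))]
    if "mu" in layout:
        out.D_star = cov[np.ix_(d_idx, _idx("mu"))]
    return out


def contrast_mean(posterior: PosteriorSummary, a: int, b: int) -> float:
    """E(d_ab) = E(d_b) - E(d_a), with E(d_1) = 0."""
    k = posterior.K
    if not (1 <= a <= k and 1 <= b <= k):
        raise ValueError(f"treatments must be in 1..{k}")
    full = posterior.mean_with_reference()
    return float(full[b - 1] - full[a - 1])
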