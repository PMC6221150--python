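"""Bias-adjustment thresholds, solution sets and decision-invariant intervals.

The treatment decision is k* = argmax_k E(d_k) (argmin for harmful
outcomes), with E(d_1) = 0 for the reference.  Adjusting a single datum y_m
by beta moves every posterior mean linearly through the influence matrix H,
so the adjustment at which an alternative treatment a ties with k* is

    u_{a,m} = (-E(d_{a k*}) - rho) / ([H]_{k*-1,m} - [H]_{a-1,m}),

where d_{a k*} = d_{k*} - d_a, rho is an optional minimal clinically
important difference, and [H]_{0,m} is read as 0 for the reference
treatment.  The positive and negative thresholds are the smallest positive
and largest negative members of the solution set {u_{a,m}}, and the new
optimum at each threshold is the treatment attaining it — no refit needed.

A common bias shared by a set M of data points sums the individual
influences, which is equivalent to combining the single-datum solutions
harmonically: u_{a,M} = (sum_{m in M} u_{a,m}^{-1})^{-1}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .influence import (
    InfluenceMatrix,
    influence_fe,
    influence_re,
)
from .network import NetworkData, PriorSpec
from .posterior import PosteriorSummary, fit_fe, fit_re_fixed_tau

__all__ = [
    "DecisionRule",
    "SolutionSet",
    "ThresholdResult",
    "optimal_treatment",
    "solution_set",
    "common_bias_solution_set",
    "thresholds_from_solutions",
    "run_study_level",
    "tau2_sensitivity",
]


@dataclass(frozen=True)
class DecisionRule:
    """Decision rule: direction of benefit and optional MCID margin rho."""

    direction: str = "higher_better"
    mcid: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in ("higher_better", "lower_better"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.mcid < 0:
            raise ValueError("mcid must be non-negative")

    @property
    def sign(self) -> float:
        """+1 when larger outcomes are better, -1 otherwise."""
        return 1.0 if self.direction == "higher_better" else -1.0


@dataclass
class SolutionSet:
    """Candidate adjustments u_a making each alternative a tie with k*."""

    m: int | frozenset
    kstar: int
    u: dict[int, float]

    def finite(self) -> dict[int, float]:
        return {a: v for a, v in self.u.items() if math.isfinite(v)}


@dataclass
class ThresholdResult:
    """Per-datum thresholds and the decision-invariant interval.

    ``beta_neg``/``beta_pos`` may be -inf/+inf, rendered 'NT' (no threshold):
    no adjustment in that direction ever changes the decision.
    """

    kstar: int
    beta_neg: float
    beta_pos: float
    new_opt_neg: int | None
    new_opt_pos: int | None
    m: int | frozenset | None = None
    label: str = ""
    estimate: float | None = None
    ci: tuple[float, float] | None = None

    @property
    def invariant_interval(self) -> tuple[float, float]:
        base = 0.0 if self.estimate is None else self.estimate
        return (base + self.beta_neg, base + self.beta_pos)

    @property
    def sensitive(self) -> bool | None:
        """True when the 95% interval extends beyond the invariant interval."""
        if self.ci is None:
            return None
        lo, hi = self.invariant_interval
        return bool(self.ci[0] < lo or self.ci[1] > hi)

    @property
    def smallest_threshold(self) -> float:
        return min(abs(self.beta_neg), abs(self.beta_pos))


def optimal_treatment(
    posterior: PosteriorSummary, rule: DecisionRule | None = None
) -> tuple[int, bool]:
    """Optimal treatment k* and a flag marking exact ties (lowest code wins)."""
    rule = rule or DecisionRule()
    scores = rule.sign * posterior.mean_with_reference()
    best = scores.max()
    tied = np.flatnonzero(scores == best)
    return int(tied[0]) + 1, tied.size > 1


def _oriented(posterior: PosteriorSummary, h: np.ndarray, rule: DecisionRule):
    """Means and influence on the 'higher is better' scale."""
    s = rule.sign
    e = s * posterior.mean_with_reference()
    return e, s * h


def _h_entry(h: np.ndarray, k: int, m: int) -> float:
    """[H]_{k-1,m} with the reference treatment contributing 0."""
    return 0.0 if k == 1 else float(h[k - 2, m])


def _u_value(num: float, den: float) -> float:
    if den == 0.0:
        return math.inf if num >= 0 else -math.inf
    return num / den


def solution_set(
    posterior: PosteriorSummary,
    influence: InfluenceMatrix | np.ndarray,
    kstar: int,
    m: int,
    rule: DecisionRule | None = None,
) -> SolutionSet:
    """Solution set {u_{a,m}} for adjustments to datum m (0-based index)."""
    rule = rule or DecisionRule()
    h = influence.H if isinstance(influence, InfluenceMatrix) else np.asarray(influence)
    if not (0 <= m < h.shape[1]):
        raise IndexError(f"datum index {m} out of range 0..{h.shape[1] - 1}")
    e, h = _oriented(posterior, h, rule)
    u: dict[int, float] = {}
    for a in range(1, posterior.K + 1):
        if a == kstar:
            continue
        num = -(e[kstar - 1] - e[a - 1]) - rule.mcid
        den = _h_entry(h, kstar, m) - _h_entry(h, a, m)
        u[a] = _u_value(num, den)
    return SolutionSet(m=m, kstar=kstar, u=u)


def common_bias_solution_set(
    posterior: PosteriorSummary,
    influence: InfluenceMatrix | np.ndarray,
    kstar: int,
    index_set,
    rule: DecisionRule | None = None,
) -> SolutionSet:
    """Solution set for one bias adjustment shared by all data in index_set.

    The shared influence is the sum over the set, which equals the harmonic
    combination of the single-datum solutions (1/inf read as 0).
    """
    rule = rule or DecisionRule()
    index_set = frozenset(int(m) for m in index_set)
    if not index_set:
        raise ValueError("index set must be non-empty")
    h = influence.H if isinstance(influence, InfluenceMatrix) else np.asarray(influence)
    for m in index_set:
        if not (0 <= m < h.shape[1]):
            raise IndexError(f"datum index {m} out of range")
    e, h = _oriented(posterior, h, rule)
    u: dict[int, float] = {}
    for a in range(1, posterior.K + 1):
        if a == kstar:
            continue
        num = -(e[kstar - 1] - e[a - 1]) - rule.mcid
        den = sum(
            _h_entry(h, kstar, m) - _h_entry(h, a, m) for m in index_set
        )
        u[a] = _u_value(num, den)
    return SolutionSet(m=index_set, kstar=kstar, u=u)


def thresholds_from_solutions(solutions: SolutionSet) -> ThresholdResult:
    """Smallest positive / largest negative solutions and the new optima.

    The new optimal treatment on each side is the alternative attaining the
    threshold (its contrast with k* is the one changing sign there), so no
    refit is required.
    """
    if not solutions.u:
        raise ValueError("empty solution set")
    beta_pos, opt_pos = math.inf, None
    beta_neg, opt_neg = -math.inf, None
    for a in sorted(solutions.u):
        v = solutions.u[a]
        if v == 0.0:
            warnings.warn(
                f"solution u_{a} is exactly 0: treatments {a} and "
                f"{solutions.kstar} are tied at zero adjustment (degenerate "
                "decision)",
                UserWarning,
                stacklevel=2,
            )
            if 0.0 < beta_pos:
                beta_pos, opt_pos = 0.0, a
        elif v > 0 and v < beta_pos:
            beta_pos, opt_pos = v, a
        elif v < 0 and v > beta_neg:
            beta_neg, opt_neg = v, a
    return ThresholdResult(
        kstar=solutions.kstar,
        beta_neg=beta_neg,
        beta_pos=beta_pos,
        new_opt_neg=opt_neg,
        new_opt_pos=opt_pos,
        m=solutions.m,
    )


def run_study_level(
    network: NetworkData,
    prior: PriorSpec | None = None,
    model: str = "fe",
    rule: DecisionRule | None = None,
    tau2: float | None = None,
    sort: bool = False,
) -> list[ThresholdResult]:
    """Study-level threshold analysis: one result per data point.

    Fits the requested model, derives the influence matrix once, and scans
    every datum m, reporting its invariant interval about the observed value
    and a 95% normal-theory CI for sensitivity flagging.
    """
    rule = rule or DecisionRule(direction=network.outcome_direction)
    if model == "fe":
        post = fit_fe(network, prior)
        infl = influence_fe(post, network)
    elif model == "re":
        if tau2 is None:
            raise ValueError("model='re' requires tau2")
        post = fit_re_fixed_tau(network, prior, tau2)
        infl = influence_re(post, network)
    else:
        raise ValueError(f"unknown model {model!r}; use 'fe' or 're'")
    kstar, _ = optimal_treatment(post, rule)
    y, v = network.y, network.V
    labels = network.datum_labels
    results = []
    for m in range(network.N):
        res = thresholds_from_solutions(
            solution_set(post, infl, kstar, m, rule)
        )
        res.label = labels[m]
        res.estimate = float(y[m])
        se = math.sqrt(v[m, m])
        res.ci = (res.estimate - 1.96 * se, res.estimate + 1.96 * se)
        results.append(res)
    if sort:
        results.sort(key=lambda r: r.smallest_threshold)
    return results


def tau2_sensitivity(
    network: NetworkData,
    tau2_values,
    prior: PriorSpec | None = None,
    rule: DecisionRule | None = None,
) -> dict[float, list[ThresholdResult]]:
    """RE thresholds over a user-supplied sweep of fixed tau^2 values.

    tau^2 is held fixed within each analysis; sweeping it (e.g. over the
    limits of its credible interval from the original fit) probes how the
    thresholds depend on the assumed heterogeneity.
    """
    out = {}
    for t2 in tau2_values:
        model = "re" if t2 > 0 else "fe"
        out[float(t2)] = run_study_level(
            network, prior, model=model, rule=rule, tau2=t2 if t2 > 0 else None
        )
    return out
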