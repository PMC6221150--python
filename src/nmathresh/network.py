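"""Evidence network data model and design/covariance matrix construction.

A network meta-analysis (NMA) synthesises trials that each compare a subset
of ``K`` treatments.  Treatment 1 is the reference; the basic parameters
``d_k`` (k = 2..K) are the relative effects of treatment k versus treatment 1,
with ``d_1 = 0``.  A study with ``A_j`` arms contributes ``A_j - 1`` relative
effects against its own baseline arm, so the stacked data vector ``y`` has
``N = sum_j (A_j - 1)`` entries with a block-diagonal within-study sampling
covariance ``V`` (multi-arm blocks carry the shared-baseline correlation).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import block_diag

from ._linalg import is_symmetric_pd

__all__ = [
    "Study",
    "NetworkData",
    "PriorSpec",
    "DisconnectedNetworkError",
    "build_design_matrix",
    "build_re_covariance",
    "read_network",
    "write_network",
]


class DisconnectedNetworkError(ValueError):
    """Network has treatments unreachable from the reference treatment."""

    def __init__(self, unreachable: set[int]):
        self.unreachable = unreachable
        super().__init__(
            "network is disconnected: treatments "
            f"{sorted(unreachable)} are unreachable from treatment 1"
        )


@dataclass
class Study:
    """One trial: ordered arm list (arm 1 = study baseline) and its data.

    ``y`` holds the ``A_j - 1`` relative effects of arms 2..A_j versus arm 1;
    ``V`` is their sampling covariance (a 1x1 block for two-arm trials).
    """

    id: str
    treatments: list[int]
    y: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.treatments = [int(t) for t in self.treatments]
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        a = len(self.treatments)
        if a < 2:
            raise ValueError(f"study {self.id}: needs at least 2 arms, got {a}")
        if len(set(self.treatments)) != a:
            raise ValueError(f"study {self.id}: duplicate treatments {self.treatments}")
        if self.y.shape != (a - 1,):
            raise ValueError(
                f"study {self.id}: expected {a - 1} relative effects, got {self.y.shape}"
            )
        if self.V.shape != (a - 1, a - 1):
            raise ValueError(
                f"study {self.id}: covariance block must be "
                f"{a - 1}x{a - 1}, got {self.V.shape}"
            )
        if not is_symmetric_pd(self.V):
            raise ValueError(
                f"study {self.id}: covariance block is not symmetric positive definite"
            )

    @property
    def n_arms(self) -> int:
        return len(self.treatments)

    @property
    def contrasts(self) -> list[tuple[int, int]]:
        """(t_i, c_i) pairs: each non-baseline arm versus the baseline arm."""
        base = self.treatments[0]
        return [(t, base) for t in self.treatments[1:]]


@dataclass
class NetworkData:
    """Full NMA evidence base: studies plus the stacked (y, V) system."""

    studies: list[Study]
    n_treatments: int | None = None
    outcome_direction: str = "higher_better"

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("network must contain at least one study")
        if self.outcome_direction not in ("higher_better", "lower_better"):
            raise ValueError(f"unknown outcome_direction {self.outcome_direction!r}")
        seen = max(max(s.treatments) for s in self.studies)
        if self.n_treatments is None:
            self.n_treatments = seen
        elif self.n_treatments < seen:
            raise ValueError(
                f"n_treatments={self.n_treatments} but treatment {seen} appears in data"
            )
        if min(min(s.treatments) for s in self.studies) < 1:
            raise ValueError("treatment codes are 1-based")
        unreachable = self._unreachable()
        if unreachable:
            raise DisconnectedNetworkError(unreachable)

    def _unreachable(self) -> set[int]:
        g = nx.Graph()
        g.add_nodes_from(range(1, self.n_treatments + 1))
        for s in self.studies:
            for t in s.treatments[1:]:
                g.add_edge(s.treatments[0], t)
        return set(range(1, self.n_treatments + 1)) - nx.node_connected_component(g, 1)

    # -- stacked system -------------------------------------------------
    @property
    def K(self) -> int:
        return int(self.n_treatments)

    @property
    def N(self) -> int:
        return sum(s.n_arms - 1 for s in self.studies)

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([s.y for s in self.studies])

    @property
    def V(self) -> np.ndarray:
        return block_diag(*[s.V for s in self.studies])

    @property
    def contrasts(self) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for s in self.studies:
            out.extend(s.contrasts)
        return out

    @property
    def datum_labels(self) -> list[str]:
        return [
            f"{s.id}: {t} vs {c}" for s in self.studies for (t, c) in s.contrasts
        ]

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Distinct undirected comparisons with direct evidence, sorted."""
        e = set()
        for s in self.studies:
            ts = s.treatments
            for i in range(len(ts)):
                for j in range(i + 1, len(ts)):
                    e.add((min(ts[i], ts[j]), max(ts[i], ts[j])))
        return sorted(e)

    def datum_study(self, m: int) -> Study:
        for s in self.studies:
            if m < s.n_arms - 1:
                return s
            m -= s.n_arms - 1
        raise IndexError("datum index out of range")


@dataclass
class PriorSpec:
    """Multivariate normal prior d ~ N(d0, Sigma_d) on the basic parameters.

    ``improper_flat`` sets the prior precision to the zero matrix, giving the
    frequentist (generalised least squares) limit.
    """

    d0: np.ndarray
    Sigma_d: np.ndarray | None = None
    improper_flat: bool = False

    def __post_init__(self) -> None:
        self.d0 = np.atleast_1d(np.asarray(self.d0, dtype=float))
        if not self.improper_flat:
            if self.Sigma_d is None:
                raise ValueError("Sigma_d required unless improper_flat")
            self.Sigma_d = np.atleast_2d(np.asarray(self.Sigma_d, dtype=float))
            if not is_symmetric_pd(self.Sigma_d):
                raise ValueError("Sigma_d must be symmetric positive definite")
            if self.Sigma_d.shape[0] != self.d0.shape[0]:
                raise ValueError("d0 and Sigma_d dimensions disagree")

    @classmethod
    def vague(cls, k: int, variance: float = 1e6) -> "PriorSpec":
        """Diffuse normal prior N(0, variance * I) on the K-1 basic effects."""
        return cls(d0=np.zeros(k - 1), Sigma_d=variance * np.eye(k - 1))

    @classmethod
    def flat(cls, k: int) -> "PriorSpec":
        return cls(d0=np.zeros(k - 1), Sigma_d=None, improper_flat=True)

    def precision(self) -> np.ndarray:
        n = self.d0.shape[0]
        if self.improper_flat:
            return np.zeros((n, n))
        return np.linalg.inv(self.Sigma_d)


# ----------------------------------------------------------------------
# matrix construction
# ----------------------------------------------------------------------

def build_design_matrix(network: NetworkData) -> np.ndarray:
    """Signed-incidence design X (N x (K-1)).

    Row i for a datum comparing t_i versus c_i has +1 in the column of
    treatment t_i and -1 in the column of c_i; columns index treatments 2..K
    (treatment 1 is the reference, d_1 = 0, and has no column).
    """
    x = np.zeros((network.N, network.K - 1))
    for i, (t, c) in enumerate(network.contrasts):
        if t == c:
            raise ValueError(f"datum {i}: treatment equals comparator ({t})")
        if t != 1:
            x[i, t - 2] = 1.0
        if c != 1:
            x[i, c - 2] = -1.0
    return x


def build_re_covariance(network: NetworkData, tau2: float) -> np.ndarray:
    """Between-study covariance Sigma_tau2 = A * tau2, block-diagonal.

    Homogeneous-heterogeneity blocks: 1 on the diagonal and 0.5 off diagonal
    for multi-arm studies (exchangeable arm-level random effects), a scalar
    for two-arm studies.
    """
    if tau2 < 0:
        raise ValueError(f"tau2 must be non-negative, got {tau2}")
    blocks = []
    for s in network.studies:
        k = s.n_arms - 1
        blocks.append(tau2 * (0.5 * np.eye(k) + 0.5 * np.ones((k, k))))
    return block_diag(*blocks)


# ----------------------------------------------------------------------
# I/O: long-format CSV
# ----------------------------------------------------------------------

def _study_frame_relative(df: pd.DataFrame, sid: str) -> Study:
    rows = df.reset_index(drop=True)
    k = len(rows)
    comps = rows["comparator"].unique()
    if len(comps) != 1:
        raise ValueError(f"study {sid}: multiple comparators {list(comps)}")
    base = int(comps[0])
    treatments = [base] + [int(t) for t in rows["treatment"]]
    v = np.diag(rows["variance"].to_numpy(dtype=float))
    for i in range(1, k):
        for j in range(i):
            col = f"cov_{j + 1}"
            if col in rows.columns and pd.notna(rows.loc[i, col]):
                v[i, j] = v[j, i] = float(rows.loc[i, col])
            elif k > 1:
                warnings.warn(
                    f"study {sid}: missing covariance between data "
                    f"{j + 1} and {i + 1}; defaulting to 0",
                    UserWarning,
                    stacklevel=3,
                )
    return Study(id=sid, treatments=treatments,
                 y=rows["estimate"].to_numpy(dtype=float), V=v)


def _study_frame_arm(df: pd.DataFrame, sid: str) -> Study:
    rows = df.reset_index(drop=True)
    est = rows["estimate"].to_numpy(dtype=float)
    var = rows["variance"].to_numpy(dtype=float)
    treatments = [int(t) for t in rows["treatment"]]
    # difference versus arm 1: shared baseline variance induces off-diagonals
    y = est[1:] - est[0]
    v = np.diag(var[1:]) + var[0]
    return Study(id=sid, treatments=treatments, y=y, V=v)


def read_network(
    path_or_buffer,
    format: str = "relative",
    outcome_direction: str = "higher_better",
) -> NetworkData:
    """Read a long-format CSV into :class:`NetworkData`.

    ``format='relative'``: one row per non-baseline arm with columns
    ``study,treatment,comparator,estimate,variance[,cov_1,cov_2,...]`` where
    ``cov_j`` is the within-study covariance with the j-th earlier datum of
    the same study.  ``format='arm'``: one row per arm with columns
    ``study,treatment,estimate,variance``; the first row of each study is the
    baseline arm and relative effects are formed by differencing against it.
    """
    df = pd.read_csv(path_or_buffer)
    if df.empty:
        raise ValueError("input table is empty")
    required = {
        "relative": ["study", "treatment", "comparator", "estimate", "variance"],
        "arm": ["study", "treatment", "estimate", "variance"],
    }
    if format not in required:
        raise ValueError(f"unknown format {format!r}")
    missing = [c for c in required[format] if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if df[["estimate", "variance"]].isna().any().any():
        bad = df.index[df[["estimate", "variance"]].isna().any(axis=1)].tolist()
        raise ValueError(f"non-numeric or missing estimate/variance in rows {bad}")
    dup = df.duplicated(subset=["study", "treatment"])
    if dup.any():
        raise ValueError(
            f"duplicate (study, treatment) rows at index {df.index[dup].tolist()}"
        )
    builder = _study_frame_relative if format == "relative" else _study_frame_arm
    studies = [
        builder(g, str(sid)) for sid, g in df.groupby("study", sort=False)
    ]
    return NetworkData(studies=studies, outcome_direction=outcome_direction)


def write_network(network: NetworkData, path_or_buffer) -> None:
    """Write relative-mode CSV; round-trips bit-identically via repr floats."""
    rows = []
    for s in network.studies:
        base = s.treatments[0]
        for i, t in enumerate(s.treatments[1:]):
            row = {
                "study": s.id,
                "treatment": t,
                "comparator": base,
                "estimate": repr(float(s.y[i])),
                "variance": repr(float(s.V[i, i])),
            }
            for j in range(i):
                row[f"cov_{j + 1}"] = repr(float(s.V[i, j]))
            rows.append(row)
    df = pd.DataFrame(rows)
    if isinstance(path_or_buffer, (str, bytes)) or hasattr(path_or_buffer, "__fspath__"):
        df.to_csv(path_or_buffer, index=False)
    else:
        assert isinstance(path_or_buffer, io.IOBase) or hasattr(path_or_buffer, "write")
        df.to_csv(path_or_buffer, index=False)
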