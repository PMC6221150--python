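"""Forest-style tables and plots of invariant intervals.

Each row shows a study or contrast estimate with its 95% interval
(confidence interval at study level, credible interval at contrast level)
and the decision-invariant bias-adjustment interval, with the new optimal
treatment at each end.  A row is flagged *sensitive* when the 95% interval
extends beyond the invariant interval: the recommendation could flip within
the imprecision of that estimate alone.  Open interval sides are rendered
'NT' (no threshold), and thresholds are printed to 2 decimals with signed
zero preserved (a "-0.00" means an infinitesimally small negative change
flips the decision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .thresholds import ThresholdResult

__all__ = ["ForestRow", "make_forest", "render", "fmt_signed"]


def fmt_signed(value: float, decimals: int = 2) -> str:
    """Fixed-point format preserving signed zero; infinities render 'NT'."""
    if math.isinf(value):
        return "NT"
    s = f"{value:.{decimals}f}"
    if float(s) == 0.0 and (value < 0 or math.copysign(1.0, value) < 0):
        if not s.startswith("-"):
            s = "-" + s
    return s


@dataclass
class ForestRow:
    label: str
    estimate: float
    ci: tuple[float, float]
    interval: tuple[float, float]
    new_opt_lo: int | None
    new_opt_hi: int | None
    sensitive: bool

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "estimate": self.estimate,
            "ci_lo": self.ci[0],
            "ci_hi": self.ci[1],
            "int_lo": self.interval[0],
            "int_hi": self.interval[1],
            "new_opt_lo": "" if self.new_opt_lo is None else self.new_opt_lo,
            "new_opt_hi": "" if self.new_opt_hi is None else self.new_opt_hi,
            "sensitive": self.sensitive,
        }


def make_forest(
    results: list[ThresholdResult],
    estimates=None,
    cis=None,
    sort: bool = True,
    filter_threshold: float | None = None,
) -> list[ForestRow]:
    """Rows for a forest display, sorted with smallest thresholds first.

    ``estimates`` and ``cis`` override the values stored on the results
    (e.g. to anchor contrast-level rows on NMA estimates).  The sensitivity
    flag is recomputed here from the raw numbers.  ``filter_threshold``
    keeps only rows whose smallest threshold is below the cutoff.
    """
    n = len(results)
    if estimates is not None and len(estimates) != n:
        raise ValueError("estimates length does not match results")
    if cis is not None and len(cis) != n:
        raise ValueError("cis length does not match results")
    rows = []
    for i, res in enumerate(results):
        est = float(estimates[i]) if estimates is not None else res.estimate
        ci = tuple(cis[i]) if cis is not None else res.ci
        if est is None or ci is None:
            raise ValueError(f"row {i}: estimate/CI unavailable")
        interval = (est + res.beta_neg, est + res.beta_pos)
        sensitive = ci[0] < interval[0] or ci[1] > interval[1]
        if res.sensitive is not None and estimates is None and cis is None:
            assert sensitive == res.sensitive
        if filter_threshold is not None and res.smallest_threshold >= filter_threshold:
            continue
        rows.append(
            ForestRow(
                label=res.label,
                estimate=est,
                ci=ci,
                interval=interval,
                new_opt_lo=res.new_opt_neg,
                new_opt_hi=res.new_opt_pos,
                sensitive=sensitive,
            )
        )
    if sort:
        order = np.argsort([
            min(abs(r.interval[0] - r.estimate), abs(r.interval[1] - r.estimate))
            for r in rows
        ], kind="stable")
        rows = [rows[i] for i in order]
    return rows


def to_frame(rows: list[ForestRow]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rows])


def render(rows: list[ForestRow], path, format: str = "csv"):
    """Write a forest table (csv/md) or plot (png/svg)."""
    if format == "csv":
        to_frame(rows).to_csv(path, index=False)
    elif format == "md":
        _render_md(rows, path)
    elif format in ("png", "svg"):
        _render_plot(rows, path, format)
    else:
        raise ValueError(f"unknown format {format!r}")


def _render_md(rows, path) -> None:
    lines = [
        "| label | estimate | 95% interval | invariant interval | new opt (lo, hi) |",
        "| --- | --- | --- | --- | --- |",
    ]
    for r in rows:
        label = f"**{r.label}**" if r.sensitive else r.label
        lines.append(
            f"| {label} | {fmt_signed(r.estimate)} "
            f"| ({fmt_signed(r.ci[0])}, {fmt_signed(r.ci[1])}) "
            f"| ({fmt_signed(r.interval[0])}, {fmt_signed(r.interval[1])}) "
            f"| {r.new_opt_lo or ''}, {r.new_opt_hi or ''} |"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _render_plot(rows, path, format) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(rows)
    fig, ax = plt.subplots(figsize=(7, max(2.0, 0.4 * n + 1.0)))
    finite = [v for r in rows for v in (*r.ci, r.estimate) if math.isfinite(v)]
    span = (max(finite) - min(finite)) if finite else 1.0
    lo_lim = (min(finite) - 0.5 * span) if finite else -1.0
    hi_lim = (max(finite) + 0.5 * span) if finite else 1.0
    for i, r in enumerate(rows):
        ypos = n - 1 - i
        band_lo = r.interval[0] if math.isfinite(r.interval[0]) else lo_lim
        band_hi = r.interval[1] if math.isfinite(r.interval[1]) else hi_lim
        ax.barh(ypos, band_hi - band_lo, left=band_lo, height=0.8,
                color="0.85", zorder=1)
        ax.plot(r.ci, [ypos, ypos], color="k", lw=1.2, zorder=2)
        ax.plot([r.estimate], [ypos], "o", mfc="white", mec="k", zorder=3)
    ax.set_yticks(range(n))
    labels = [r.label for r in rows][::-1]
    ax.set_yticklabels(labels)
    for tick, r in zip(ax.get_yticklabels(), rows[::-1]):
        if r.sensitive:
            tick.set_fontweight("bold")
    ax.set_xlim(lo_lim, hi_lim)
    ax.set_xlabel("effect estimate (shaded: invariant interval)")
    fig.tight_layout()
    fig.savefig(path, format=format, dpi=150)
    plt.close(fig)
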