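"""Collinearity screening of predictor layers.

Predictors that are strongly correlated inflate each other's apparent
importance and destabilize coefficient estimates.  The filter here keeps,
from every highly correlated pair (|r| >= 0.8 by default), the member with
the higher model contribution, after first discarding predictors that
contribute nothing at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid_io import GridLayer
from .stack import joint_valid_mask

__all__ = ["SelectionReport", "correlation_matrix", "select_variables"]


@dataclass
class SelectionReport:
    kept: list[str] = field(default_factory=list)
    dropped: list[tuple[str, str, float, str]] = field(default_factory=list)
    # (name, partner, r, reason)
    correlation: pd.DataFrame | None = None

    def write_report(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kept\t" + ",".join(self.kept) + "\n")
            for name, partner, r, reason in self.dropped:
                fh.write(f"dropped\t{name}\tpartner={partner}\tr={r:.4f}\t{reason}\n")

    def write_matrix(self, path) -> None:
        if self.correlation is not None:
            self.correlation.to_csv(path)


def correlation_matrix(layers: list[GridLayer]) -> pd.DataFrame:
    """Pairwise product-moment correlation over jointly valid cells.

    A zero-variance layer yields NaN against every partner (flagged, never
    silently zero); the diagonal is exactly 1.  Requires >= 2 layers and
    >= 3 jointly valid cells.
    """
    if len(layers) < 2:
        raise ValueError("need at least 2 layers")
    mask = joint_valid_mask(layers)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 jointly valid cells")
    names = [lyr.name or f"var{i}" for i, lyr in enumerate(layers)]
    X = np.column_stack([lyr.values[mask] for lyr in layers])
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=names, columns=names)


def select_variables(
    layers: list[GridLayer],
    contributions: dict[str, float],
    r_threshold: float = 0.8,
) -> SelectionReport:
    """Contribution-aware collinearity filter.

    First drops layers whose contribution is <= 0.  Then, while any
    remaining pair has |r| >= ``r_threshold``, removes from the most
    correlated such pair the member with the lower contribution (ties:
    the later layer in input order is dropped).  Deterministic given the
    contributions.
    """
    names = [lyr.name or f"var{i}" for i, lyr in enumerate(layers)]
    missing = [n for n in names if n not in contributions]
    if missing:
        raise ValueError(f"missing contributions for: {missing}")
    corr = correlation_matrix(layers)
    report = SelectionReport(correlation=corr)

    active = []
    for n in names:
        if contributions[n] <= 0:
            report.dropped.append((n, "", float("nan"), "contribution <= 0"))
        else:
            active.append(n)

    order = {n: i for i, n in enumerate(names)}
    while True:
        best_pair = None
        best_r = 0.0
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                r = corr.loc[a, b]
                if np.isfinite(r) and abs(r) >= r_threshold and abs(r) > abs(best_r):
                    best_r = r
                    best_pair = (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        if contributions[a] < contributions[b]:
            victim, partner = a, b
        elif contributions[b] < contributions[a]:
            victim, partner = b, a
        else:  # tie: later in input order goes
            victim, partner = (b, a) if order[b] > order[a] else (a, b)
        active.remove(victim)
        report.dropped.append(
            (victim, partner, float(best_r),
             f"|r| >= {r_threshold} with lower contribution")
        )
    report.kept = active
    return report
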