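"""Univariable case-control screening of ordered disease triplets.

Each supported triplet is tested for association with case status by a
single-covariate logistic regression of case status on exposure. With one
binary covariate the maximum-likelihood odds ratio equals the 2x2
cross-product ratio (a*d)/(b*c), and the Wald statistic is
log(OR) / sqrt(1/a + 1/b + 1/c + 1/d), so both are computed in closed form.
Triplets pass the screen iff OR > 1 and the two-sided Wald p < alpha; no
multiplicity adjustment is applied at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import Triplet, TripletCluster


@dataclass
class ScreenRecord:
    """Screening result for one ordered triplet."""

    triplet: Triplet
    odds_ratio: float  # nan when non-estimable (zero cell)
    p_value: float
    estimable: bool
    selected: bool


def _wald(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    or_ = (a * d) / (b * c)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = np.log(or_) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(or_), float(p)


def screen_triplet(cluster: TripletCluster, alpha: float = 0.05) -> ScreenRecord:
    """Screen one triplet's 2x2 exposure table against case status.

    Any zero cell makes the odds ratio non-estimable (logistic separation);
    such records are flagged and never selected — no continuity correction
    is applied.
    """
    a, b = cluster.n_case_exposed, cluster.n_case_unexposed
    c, d = cluster.n_ctrl_exposed, cluster.n_ctrl_unexposed
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if min(a, b, c, d) == 0:
        return ScreenRecord(cluster.triplet, float("nan"), float("nan"), False, False)
    or_, p = _wald(a, b, c, d)
    return ScreenRecord(cluster.triplet, or_, p, True, or_ > 1.0 and p < alpha)


def screen_support_table(support: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Vectorised screening of a triplet-support table.

    Adds odds_ratio, p_value, estimable and selected columns to the table
    produced by :func:`dxpath.preprocessing.count_support`.
    """
    out = support.copy()
    a = out["n_case_exposed"].to_numpy(dtype=float)
    b = out["n_case_unexposed"].to_numpy(dtype=float)
    c = out["n_ctrl_exposed"].to_numpy(dtype=float)
    d = out["n_ctrl_unexposed"].to_numpy(dtype=float)
    estimable = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    or_ = np.full(len(out), np.nan)
    p = np.full(len(out), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        or_[estimable] = (a[estimable] * d[estimable]) / (b[estimable] * c[estimable])
        se = np.sqrt(
            1.0 / a[estimable] + 1.0 / b[estimable] + 1.0 / c[estimable] + 1.0 / d[estimable]
        )
        z = np.log(or_[estimable]) / se
        p[estimable] = 2.0 * stats.norm.sf(np.abs(z))
    out["odds_ratio"] = or_
    out["p_value"] = p
    out["estimable"] = estimable
    out["selected"] = estimable & (or_ > 1.0) & (p < alpha)
    return out


def select_pathways(screened: pd.DataFrame, alpha: float = 0.05) -> set[Triplet]:
    """Positively associated pathways: OR > 1 and p < alpha, estimable only."""
    if "odds_ratio" not in screened.columns:
        screened = screen_support_table(screened, alpha=alpha)
    mask = (
        screened["estimable"]
        & (screened["odds_ratio"] > 1.0)
        & (screened["p_value"] < alpha)
    )
    sel = screened.loc[mask, ["d1", "d2", "d3"]]
    return set(map(tuple, sel.to_numpy()))
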