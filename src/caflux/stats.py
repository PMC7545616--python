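"""Group statistics on experimental units: mean ± SEM and one-way ANOVA.

The experimental unit is the coverslip (evoked assay) or the independent
experiment (plate assay) — never the cell or the well, whose pseudo-
replication would inflate significance. Tables carry a ``unit_type`` column
and cell/well-level input is refused.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DesignError, ExclusionError

__all__ = [
    "AnovaResult",
    "apply_exclusions",
    "summarize_groups",
    "one_way_anova",
    "pairwise_tukey",
    "significance_stars",
]

logger = logging.getLogger(__name__)

_FORBIDDEN_UNITS = {"cell", "well"}
# display-only star convention
_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _check_units(units: pd.DataFrame) -> None:
    if "unit_type" in units.columns:
        bad = set(units["unit_type"].unique()) & _FORBIDDEN_UNITS
        if bad:
            raise DesignError(
                f"statistics must run on experimental units (coverslips/"
                f"experiments), got unit_type={sorted(bad)}; aggregate first"
            )
    for col in ("unit_id", "group"):
        if col not in units.columns:
            raise DesignError(f"metric table needs a {col!r} column")


def apply_exclusions(
    units: pd.DataFrame, exclusions: list[str]
) -> pd.DataFrame:
    """Drop explicitly excluded units; every removal is logged by id.

    Exclusion is manual and auditable only — there is no automatic outlier
    rejection anywhere in the pipeline.
    """
    if not exclusions:
        return units.copy()
    known = set(units["unit_id"])
    unknown = [e for e in exclusions if e not in known]
    if unknown:
        raise ExclusionError(f"unknown unit ids in exclusion list: {unknown}")
    logger.info("excluding units: %s", list(exclusions))
    return units[~units["unit_id"].isin(set(exclusions))].copy()


def summarize_groups(units: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-group n, mean and SEM (sd/sqrt(n), ddof=1) of ``metric``.

    A group with fewer than two units gets SEM = NaN and a degenerate-group
    warning rather than an error.
    """
    _check_units(units)
    if metric not in units.columns:
        raise DesignError(f"no metric column {metric!r}")
    out = (
        units.groupby("group", sort=True)[metric]
        .agg(n="size", mean="mean",
             sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
        .reset_index()
    )
    small = out.loc[out["n"] < 2, "group"].tolist()
    if small:
        warnings.warn(
            f"groups with < 2 experimental units, SEM undefined: {small}",
            UserWarning,
            stacklevel=2,
        )
    return out


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int

    def __iter__(self):
        return iter((self.f, self.p))


def one_way_anova(units: pd.DataFrame, metric: str) -> AnovaResult:
    """One-way fixed-effects ANOVA across groups of experimental units.

    Standard between/within sum-of-squares decomposition; F on
    ``(k - 1, N - k)`` degrees of freedom with the upper-tail p-value. With
    zero within-group variance the statistic degenerates cleanly: perfect
    separation gives ``F = inf, p = 0``; all values identical gives
    ``F = 0, p = 1``.
    """
    _check_units(units)
    groups = [g[metric].to_numpy(float) for _, g in units.groupby("group")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DesignError(
            "one-way ANOVA needs >= 2 groups with >= 2 units each"
        )
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = n_total - len(groups)
    if ss_within == 0.0:
        f = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(f=float(f), p=p, df_between=df_b, df_within=df_w)


def pairwise_tukey(units: pd.DataFrame, metric: str, alpha: float = 0.05):
    """Optional Tukey HSD post-hoc comparison (off by default).

    Returns the statsmodels ``TukeyHSDResults`` object.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    _check_units(units)
    return pairwise_tukeyhsd(
        units[metric].to_numpy(float), units["group"].to_numpy(), alpha=alpha
    )


def significance_stars(p: float) -> str:
    """Display stars at the 0.05 / 0.01 / 0.001 levels ('ns' otherwise)."""
    for level, stars in _STAR_LEVELS:
        if p < level:
            return stars
    return "ns"
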