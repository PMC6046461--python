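"""Phenotype statistics reconstructed from printed summary data.

Published phenotype tables report only per-group mean, SEM and n, yet
both the two-factor ANOVA and pairwise comparisons are fully
determined by those summaries: the within-cell sum of squares is
sum (n_i - 1) n_i SEM_i^2 (since SD_i = SEM_i sqrt(n_i)) and the
between-cell structure depends only on cell means and sizes. This
module fits the 2x2 age x disease factorial by weighted least squares
on the cell means with effect coding and reports Type III (marginal)
sums of squares — the behaviour of the commercial packages usually
used for such tables — together with the percent-of-total-variation
per effect, and provides the Welch two-sample t from summaries plus
per-family Benjamini-Hochberg adjustment.

Any full dataset whose cells realize the stated means and SDs yields
exactly the same ANOVA and t results, which is the basis of the
full-data reconstruction oracle used in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gscontrast.diffexpr import bh_adjust
from gscontrast.io import SummaryStatsTable

#: canonical 2x2 cell order: (age, disease) effect-coded -1/+1
GRID = ("young-sham", "young-DOCA", "aging-sham", "aging-DOCA")
_AGE = np.array([-1.0, -1.0, 1.0, 1.0])
_DIS = np.array([-1.0, 1.0, -1.0, 1.0])


@dataclass
class AnovaSummaryResult:
    """Two-factor ANOVA decomposition for one endpoint.

    ``effects`` maps {"age", "disease", "interaction"} to dicts with
    ss, percent_variation, f_stat and p; residual ss/df and the total
    ss are carried alongside.
    """

    endpoint: str
    effects: dict[str, dict[str, float]]
    ss_residual: float
    df_residual: int
    ss_total: float

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"endpoint": self.endpoint}
        for name in ("interaction", "age", "disease"):
            e = self.effects[name]
            row[f"{name}_percent"] = e["percent_variation"]
            row[f"{name}_p"] = e["p"]
        return row


@dataclass
class SummaryTResult:
    """Welch two-sample t-test computed from mean/SEM/n summaries."""

    t: float
    df: float
    p: float


def _cells_in_grid_order(
    grid: dict[str, tuple[float, float, int]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    missing = [g for g in GRID if g not in grid]
    if missing:
        raise ValueError(f"incomplete 2x2 grid; missing cells {missing}")
    means = np.array([grid[g][0] for g in GRID], dtype=float)
    sems = np.array([grid[g][1] for g in GRID], dtype=float)
    ns = np.array([grid[g][2] for g in GRID], dtype=float)
    if (ns < 2).any():
        raise ValueError("every cell needs n >= 2")
    return means, sems, ns


def anova_from_summaries(
    table: SummaryStatsTable, endpoint: str | None = None
) -> AnovaSummaryResult | list[AnovaSummaryResult]:
    """Two-factor ANOVA with Type III SS from a 2x2 summary grid.

    For each endpoint the within-cell SS is reconstructed from the
    SEMs, the saturated cell-mean model is fit by n-weighted least
    squares with effect coding, and each effect's Type III SS is the
    increase in weighted residual SS when that term is dropped (the
    interaction kept). percent_variation = 100 SS_effect / SS_total
    with SS_total = between + within; F tests use the residual mean
    square on N - 4 degrees of freedom.
    """
    if endpoint is None:
        return [anova_from_summaries(table, e) for e in table.endpoints]
    means, sems, ns = _cells_in_grid_order(table.grid(endpoint))
    ss_within = float(np.sum((ns - 1) * ns * sems**2))
    df_res = int(ns.sum()) - 4
    x_full = np.column_stack([np.ones(4), _AGE, _DIS, _AGE * _DIS])
    w = np.sqrt(ns)

    def wrss(x: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(x * w[:, None], means * w, rcond=None)
        resid = means - x @ beta
        return float(np.sum(ns * resid**2))

    rss_full = wrss(x_full)  # zero: the saturated model fits 4 cells exactly
    grand = float(np.sum(ns * means) / ns.sum())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_total = ss_between + ss_within
    ms_res = ss_within / df_res

    effects: dict[str, dict[str, float]] = {}
    for column, name in ((1, "age"), (2, "disease"), (3, "interaction")):
        ss = wrss(np.delete(x_full, column, axis=1)) - rss_full
        f = ss / ms_res if ms_res > 0 else np.inf
        p = float(stats.f.sf(f, 1, df_res)) if np.isfinite(f) else 0.0
        effects[name] = {
            "ss": ss,
            "percent_variation": 100.0 * ss / ss_total if ss_total > 0 else 0.0,
            "f_stat": f,
            "p": max(p, np.finfo(float).tiny),
        }
    return AnovaSummaryResult(endpoint, effects, ss_within, df_res, ss_total)


def welch_t_from_summaries(
    mean1: float,
    sem1: float,
    n1: int,
    mean2: float,
    sem2: float,
    n2: int,
) -> SummaryTResult:
    """Welch two-sample t-test from per-group mean, SEM and n.

    t = (mean2 - mean1)/sqrt(sem1^2 + sem2^2) with Welch-Satterthwaite
    degrees of freedom and a two-sided p-value.
    """
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    v1, v2 = sem1**2, sem2**2
    t = (mean2 - mean1) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return SummaryTResult(float(t), float(df), max(p, np.finfo(float).tiny))


def family_bh(families: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
    """Benjamini-Hochberg adjustment applied within each endpoint family.

    ``families`` maps family name -> {endpoint: p}; the result has the
    same shape with q-values.
    """
    out: dict[str, dict[str, float]] = {}
    for family, ps in families.items():
        if not ps:
            raise ValueError(f"family {family!r} is empty")
        names = list(ps)
        q = bh_adjust(np.array([ps[n] for n in names], dtype=float))
        out[family] = {n: float(v) for n, v in zip(names, q)}
    return out


def anova_table(results: list[AnovaSummaryResult]) -> pd.DataFrame:
    """Tabulate ANOVA results in the printed-table column layout."""
    return pd.DataFrame([r.to_row() for r in results])
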