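"""Gsheat: per-sample rank-sum gene-set activation scores.

Within each sample, genes are ranked from least expressed (rank 1) to
most expressed (rank N); ties receive average ranks, so every sample's
ranks sum to N(N+1)/2 exactly. A set's score in a sample is the sum of
its member genes' ranks — bounded by [k(k+1)/2, k(2N-k+1)/2] for a set
with k members present. Because ranks are invariant under any
per-sample monotone transform of the counts, the scores are identical
whether computed on raw counts, CPM or log counts; ranks are therefore
taken on raw counts and no normalization is applied.

Differential set activation between two groups is tested on the score
matrix with a moderated t-statistic: per-set variances are shrunk
toward a pooled prior whose scale and degrees of freedom are estimated
across sets by moment matching of the variance distribution (on the
log scale, the standard empirical-Bayes construction). With fewer than
10 sets the ordinary two-sample t is used instead.

Reporting helpers order the top sets for a yellow-high / red-low heat
map and export node/edge tables (Jaccard overlap) for enrichment-map
style network tools.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from gscontrast.diffexpr import bh_adjust
from gscontrast.io import CountMatrix, GeneSetCollection, SampleSheet

logger = logging.getLogger(__name__)


@dataclass
class SetScoreMatrix:
    """Gene-sets x samples rank-sum scores.

    ``scores`` rows are sets, columns samples; ``member_count_used``
    records how many members of each set were present in the count
    matrix; ``n_genes`` is the size of the ranked universe, needed for
    the normalized score raw / [k(N+1)/2] whose null expectation is 1.
    """

    set_names: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    member_count_used: dict[str, int]
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.set_names, columns=self.sample_ids)

    def normalized(self) -> pd.DataFrame:
        """Scores divided by their null expectation k(N+1)/2."""
        k = np.array([self.member_count_used[s] for s in self.set_names], dtype=float)
        expect = k * (self.n_genes + 1) / 2.0
        return self.to_frame().div(expect, axis=0)


@dataclass
class DifferentialSetResult:
    """Per-set two-group test on Gsheat scores."""

    group_a: str
    group_b: str
    method: str
    table: pd.DataFrame  # index set; mean_a, mean_b, t, p, fdr


def rank_within_sample(counts: CountMatrix) -> np.ndarray:
    """Per-sample ascending ranks (1..N) with average ties.

    Column j of the result ranks the counts of sample j; each column
    sums to N(N+1)/2 exactly thanks to the average-tie policy.
    """
    if counts.n_genes < 2:
        raise ValueError("ranking needs at least 2 genes")
    return np.apply_along_axis(stats.rankdata, 0, counts.counts.astype(float))


def set_score_matrix(
    counts: CountMatrix,
    collection: GeneSetCollection,
    min_members: int = 2,
) -> SetScoreMatrix:
    """Rank-sum score of every set in every sample.

    Sets with fewer than ``min_members`` genes present in the matrix
    are skipped with a warning; absent members contribute nothing and
    their number is recorded via ``member_count_used``.
    """
    collection.coverage_warning(counts)
    ranks = rank_within_sample(counts)
    pos = {g: i for i, g in enumerate(counts.gene_ids)}
    names: list[str] = []
    rows: list[np.ndarray] = []
    used: dict[str, int] = {}
    skipped = 0
    for name, members in collection.items():
        idx = [pos[g] for g in members if g in pos]
        if len(idx) < min_members:
            skipped += 1
            continue
        names.append(name)
        used[name] = len(idx)
        rows.append(ranks[idx].sum(axis=0))
    if skipped:
        warnings.warn(
            f"{skipped} gene sets had fewer than {min_members} members in the "
            "count matrix and were skipped",
            stacklevel=2,
        )
    if not names:
        raise ValueError("no gene set survived intersection with the count matrix")
    return SetScoreMatrix(
        names, list(counts.sample_ids), np.vstack(rows), used, counts.n_genes
    )


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for variances by moment matching.

    Matches the first two moments of log(s2) to a scaled F / log
    chi-square model (digamma/trigamma inversion); returns
    (prior_df, prior_var). prior_df = inf when the observed spread of
    log-variances does not exceed the chi-square sampling spread.
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = z.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))

    # solve trigamma(d0/2) = excess for d0 by bisection
    def f(d0: float) -> float:
        return special.polygamma(1, d0 / 2) - excess

    lo, hi = 1e-3, 1e6
    if f(hi) > 0:
        return np.inf, float(np.exp(e_mean))
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    d0 = 0.5 * (lo + hi)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def differential_sets(
    scores: SetScoreMatrix,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    method: str = "moderated_t",
) -> DifferentialSetResult:
    """Two-sample test per set on the score matrix (B minus A).

    ``moderated_t`` shrinks per-set pooled variances toward an
    empirical-Bayes prior estimated across sets and tests against a
    t distribution with augmented degrees of freedom; ``ordinary_t``
    is the textbook pooled-variance two-sample t.
    """
    if method not in ("moderated_t", "ordinary_t"):
        raise ValueError(f"unknown method {method!r}")
    samples_a = sheet.samples_in_group(group_a)
    samples_b = sheet.samples_in_group(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    col = {s: j for j, s in enumerate(scores.sample_ids)}
    xa = scores.scores[:, [col[s] for s in samples_a]].astype(float)
    xb = scores.scores[:, [col[s] for s in samples_b]].astype(float)
    n_a, n_b = xa.shape[1], xb.shape[1]
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    df = n_a + n_b - 2
    s2 = ((n_a - 1) * xa.var(axis=1, ddof=1) + (n_b - 1) * xb.var(axis=1, ddof=1)) / df
    se_unit = np.sqrt(1.0 / n_a + 1.0 / n_b)

    used = method
    if method == "moderated_t" and len(scores.set_names) < 10:
        used = "ordinary_t"
        logger.info("fewer than 10 sets: falling back to the ordinary t-test")

    if used == "ordinary_t":
        post_s2, post_df = s2, float(df)
    else:
        d0, s0_sq = _fit_variance_prior(s2, df)
        if np.isinf(d0):
            post_s2 = np.full_like(s2, s0_sq)
            post_df = 1e6
        else:
            post_s2 = (d0 * s0_sq + df * s2) / (d0 + df)
            post_df = float(d0 + df)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_b - mean_a) / (np.sqrt(post_s2) * se_unit)
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2 * stats.t.sf(np.abs(t), post_df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t_moderated": t,
            "p": p,
            "fdr": bh_adjust(p),
            "size_used": [scores.member_count_used[s] for s in scores.set_names],
        },
        index=pd.Index(scores.set_names, name="set_name"),
    )
    return DifferentialSetResult(group_a, group_b, used, table)


def top_sets_heatmap(
    scores: SetScoreMatrix,
    diffresult: DifferentialSetResult,
    n_top: int = 50,
    figure_path: str | Path | None = None,
):
    """Ordered z-scored submatrix of the top sets, optionally rendered.

    Takes the ``n_top`` sets with smallest p, z-scores each row across
    samples, clusters rows and columns by average-linkage Euclidean
    hierarchical clustering, and returns the reordered DataFrame. When
    ``figure_path`` is given a yellow-high / red-low heat map is saved.
    """
    if n_top > len(diffresult.table):
        raise ValueError("n_top exceeds the number of tested sets")
    top = diffresult.table.nsmallest(n_top, "p").index
    frame = scores.to_frame().loc[top].astype(float)
    vals = frame.to_numpy()
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (vals - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    zed = pd.DataFrame(z, index=frame.index, columns=frame.columns)

    row_order = np.arange(len(zed))
    col_order = np.arange(zed.shape[1])
    if len(zed) >= 2:
        row_order = hierarchy.leaves_list(
            hierarchy.linkage(pdist(z), method="average")
        )
    if zed.shape[1] >= 2:
        col_order = hierarchy.leaves_list(
            hierarchy.linkage(pdist(z.T), method="average")
        )
    ordered = zed.iloc[row_order, col_order]

    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.4 * ordered.shape[1] + 2), max(3, 0.22 * len(ordered) + 1))
        )
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="hot", interpolation="nearest")
        ax.set_xticks(range(ordered.shape[1]))
        ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(ordered)))
        ax.set_yticklabels(ordered.index, fontsize=5)
        fig.colorbar(im, ax=ax, label="row z-score")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return ordered


def export_enrichment_map(
    diffresult: DifferentialSetResult,
    collection: GeneSetCollection,
    fdr_cut: float = 0.05,
    jaccard_cut: float = 0.25,
    node_path: str | Path | None = None,
    edge_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for an enrichment-map style network.

    Nodes are sets below ``fdr_cut`` (attributes: fdr, direction from
    the sign of the moderated t); edges connect node pairs whose member
    Jaccard overlap reaches ``jaccard_cut``. Tables are returned and,
    when paths are given, written as TSV importable by graph tools.
    """
    sig = diffresult.table[diffresult.table["fdr"] < fdr_cut]
    nodes = pd.DataFrame(
        {
            "set_name": sig.index,
            "fdr": sig["fdr"].to_numpy(),
            "direction": np.where(sig["t_moderated"] >= 0, "up", "down"),
        }
    )
    members = {name: set(collection[name]) for name in sig.index if name in collection.sets}
    edges_rows = []
    names = list(members)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = members[names[i]], members[names[j]]
            union = a | b
            jac = len(a & b) / len(union) if union else 0.0
            if jac >= jaccard_cut:
                edges_rows.append(
                    {"source": names[i], "target": names[j], "jaccard": jac}
                )
    edges = pd.DataFrame(edges_rows, columns=["source", "target", "jaccard"])
    if node_path is not None:
        nodes.to_csv(node_path, sep="\t", index=False)
    if edge_path is not None:
        edges.to_csv(edge_path, sep="\t", index=False)
    return nodes, edges
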