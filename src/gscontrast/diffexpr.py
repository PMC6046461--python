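"""Per-contrast differential expression for NB count data.

The stage mirrors the classic two-group exact-test workflow for bulk
RNA-seq: low-count filtering (genes with a mean below 10 reads per
sample are dropped), trimmed-mean-of-M-values (TMM) scale factors,
a negative-binomial exact test on library-size-equalized pseudo-counts
with a method-of-moments dispersion estimate, Benjamini-Hochberg FDR,
and the signed inverse-p ranking metric

    rank_score = sign(log2FC) * 1 / p

that orders genes from most up- to most down-regulated for the
enrichment stages. Cross-contrast comparison utilities (Venn counts,
rank-rank histogram) and a PCA reporting helper round out the module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gscontrast.io import CountMatrix, SampleSheet

logger = logging.getLogger(__name__)

#: floor applied to p-values before inversion so rank scores stay finite
P_FLOOR = 1e-300


@dataclass
class NormalizationFactors:
    """Per-sample library sizes and TMM scale factors (geometric mean 1)."""

    sample_ids: list[str]
    library_sizes: np.ndarray
    scale_factors: np.ndarray

    @property
    def effective_sizes(self) -> np.ndarray:
        return self.library_sizes * self.scale_factors


@dataclass
class ContrastResult:
    """Per-gene statistics for one two-group contrast (B over A)."""

    group_a: str
    group_b: str
    table: pd.DataFrame  # index gene_id; mean_count, log2fc, p_value, fdr, rank_score

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] < fdr]

    def ranked_gene_list(self) -> pd.Series:
        """Rank scores ordered most up-regulated first, ties broken
        deterministically by |log2FC| descending then gene id."""
        t = self.table
        key = sorted(
            range(len(t)),
            key=lambda i: (
                -t["rank_score"].iloc[i],
                -abs(t["log2fc"].iloc[i]),
                t.index[i],
            ),
        )
        return t["rank_score"].iloc[key]


def filter_low_counts(counts: CountMatrix, min_mean: float = 10.0) -> CountMatrix:
    """Drop genes whose mean count across all samples is below ``min_mean``.

    The rule excludes strictly-below-threshold genes, so a gene
    averaging exactly 10 reads per sample is retained.
    """
    means = counts.counts.mean(axis=1)
    keep = means >= min_mean
    if not keep.any():
        warnings.warn("low-count filter removed every gene", stacklevel=2)
    logger.info(
        "low-count filter: %d of %d genes retained (min mean %g)",
        int(keep.sum()),
        counts.n_genes,
        min_mean,
    )
    return counts.subset_genes(keep)


def tmm_factors(
    counts: CountMatrix,
    trim_logratio: float = 0.3,
    trim_abundance: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scale factors.

    The reference is the sample whose upper-quartile count is closest
    to the mean upper quartile. For each sample, M-values (log2 ratio
    of library-size-normalized counts against the reference) and
    A-values (mean log2 abundance) are computed over genes expressed
    in both; the top/bottom ``trim_logratio`` fraction by M and
    ``trim_abundance`` fraction by A are discarded and the factor is
    2**mean(M) of the survivors, rescaled so factors have geometric
    mean 1.
    """
    y = counts.counts.astype(float)
    lib = y.sum(axis=0)
    for j, tot in enumerate(lib):
        if tot <= 0:
            raise ValueError(f"sample {counts.sample_ids[j]!r} has zero total counts")
    uq = np.percentile(y, 75, axis=0) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(counts.n_samples)
    for j in range(counts.n_samples):
        if j == ref:
            continue
        factors[j] = _tmm_pair(y[:, j], lib[j], y[:, ref], lib[ref], trim_logratio, trim_abundance)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(list(counts.sample_ids), lib, factors)


def _tmm_pair(
    obs: np.ndarray,
    n_obs: float,
    ref: np.ndarray,
    n_ref: float,
    trim_logratio: float,
    trim_abundance: float,
) -> float:
    both = (obs > 0) & (ref > 0)
    if both.sum() < 1:
        return 1.0
    p_obs = obs[both] / n_obs
    p_ref = ref[both] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    if np.allclose(m, m[0]):
        return float(2 ** m[0])
    keep = _double_trim(m, trim_logratio) & _double_trim(a, trim_abundance)
    if not keep.any():
        keep = np.ones_like(m, dtype=bool)
    return float(2 ** m[keep].mean())


def _double_trim(x: np.ndarray, frac: float) -> np.ndarray:
    lo, hi = np.quantile(x, [frac, 1 - frac])
    return (x >= lo) & (x <= hi)


def signed_inverse_p_rank(log2fc: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Signed inverse-p score: sign(log2FC)/p, 0 where log2FC is 0.

    p-values are floored at ``P_FLOOR`` (and at the smallest positive
    p observed, whichever is larger) so the score stays finite.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    positive = p[p > 0]
    floor = max(P_FLOOR, positive.min() if positive.size else P_FLOOR)
    p_safe = np.maximum(p, floor)
    return np.sign(log2fc) / p_safe


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped to 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------


def _equalize_libraries(y: np.ndarray, eff_sizes: np.ndarray) -> np.ndarray:
    """Scale counts to a common (geometric-mean) effective library size."""
    target = np.exp(np.mean(np.log(eff_sizes)))
    return y * (target / eff_sizes)[None, :]


def _mom_common_dispersion(pseudo: np.ndarray, groups: list[np.ndarray]) -> float:
    """Pooled method-of-moments dispersion from var = mu + phi mu^2.

    Ratio estimator across genes of within-group (variance - mean)
    against squared mean, which is stable even at n = 4 per group.
    """
    num = 0.0
    den = 0.0
    for idx in groups:
        sub = pseudo[:, idx]
        n = sub.shape[1]
        if n < 2:
            continue
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        w = n - 1
        num += w * float(np.sum(var - mu))
        den += w * float(np.sum(mu**2))
    if den <= 0:
        return 0.0
    return max(num / den, 0.0)


def _mom_genewise_dispersion(pseudo: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    mu_sum = np.zeros(pseudo.shape[0])
    num = np.zeros(pseudo.shape[0])
    den = np.zeros(pseudo.shape[0])
    for idx in groups:
        sub = pseudo[:, idx]
        n = sub.shape[1]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        num += (n - 1) * (var - mu)
        den += (n - 1) * mu**2
        mu_sum += mu
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return np.maximum(phi, 0.0)


def _mom_trended_dispersion(
    pseudo: np.ndarray, groups: list[np.ndarray], bin_size: int = 100
) -> np.ndarray:
    """Mean-dependent dispersion: pooled MoM within abundance bins.

    Genes are binned by overall mean (about ``bin_size`` genes per
    bin); each bin gets the pooled ratio estimator of phi and the
    per-gene trend value is interpolated on the log-mean axis. This
    accommodates the var = mu + phi(mu) mu^2 shape of real count data,
    where low-abundance genes are substantially more dispersed.
    """
    n_genes = pseudo.shape[0]
    overall = pseudo.mean(axis=1)
    order = np.argsort(overall, kind="mergesort")
    n_bins = max(1, n_genes // bin_size)
    bins = np.array_split(order, n_bins)
    bin_mu = np.empty(len(bins))
    bin_phi = np.empty(len(bins))
    for b, idx in enumerate(bins):
        bin_mu[b] = overall[idx].mean()
        bin_phi[b] = _mom_common_dispersion(pseudo[idx], groups)
    log_mu = np.log(np.maximum(overall, 1e-8))
    phi = np.interp(log_mu, np.log(np.maximum(bin_mu, 1e-8)), bin_phi)
    return np.maximum(phi, 0.0)


def exact_nb_pvalue(
    sum_a: float, sum_b: float, n_a: int, n_b: int, dispersion: float
) -> float:
    """Two-sided NB exact-test p-value for a single gene.

    Conditions on the total ``sum_a + sum_b``: under NB group sums
    (group j total ~ NB with mean n_j*mu and dispersion phi/n_j), the
    p-value is the conditional probability of splits with point
    probability at or below that of the observed split. At zero
    dispersion this reduces to the conditional binomial test.
    """
    a = int(round(sum_a))
    b = int(round(sum_b))
    s = a + b
    if s == 0:
        return 1.0
    mu = s / (n_a + n_b)
    k = np.arange(s + 1)
    if dispersion <= 1e-12:
        # Poisson limit: conditional distribution is Binomial(s, n_a/(n_a+n_b))
        logp = stats.binom.logpmf(k, s, n_a / (n_a + n_b))
    else:
        r_a = n_a / dispersion
        r_b = n_b / dispersion
        mean_a, mean_b = n_a * mu, n_b * mu
        logp_a = stats.nbinom.logpmf(k, r_a, r_a / (r_a + mean_a))
        logp_b = stats.nbinom.logpmf(s - k, r_b, r_b / (r_b + mean_b))
        logp = logp_a + logp_b
        logp = logp - logsumexp_stable(logp)
    p_obs = logp[a]
    mask = logp <= p_obs + 1e-10
    return float(min(1.0, np.exp(logsumexp_stable(logp[mask]))))


def logsumexp_stable(logx: np.ndarray) -> float:
    from scipy.special import logsumexp

    return float(logsumexp(logx))


def nb_exact_contrast(
    counts: CountMatrix,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    dispersion_mode: str = "trended",
    prior_df: float = 20.0,
    prior_count: float = 0.5,
) -> ContrastResult:
    """NB exact-test differential expression of ``group_b`` over ``group_a``.

    Groups are ``age-treatment`` labels from the sample sheet (e.g.
    ``young-sham`` vs ``young-DOCA``). Counts are scaled to a common
    effective library size (TMM x library size, geometric mean), the
    dispersion is estimated by pooled method of moments — on the whole
    matrix (``common``), within abundance bins interpolated per gene
    (``trended``, the default), or gene-wise shrunk toward the trend
    with ``prior_df`` prior degrees of freedom (``shrunk``) — and
    per-gene two-sided p-values come from the
    conditional NB exact test. log2 fold changes use a ``prior_count``
    offset on normalized group means; FDR is Benjamini-Hochberg; the
    rank score is the signed inverse p-value.
    """
    if dispersion_mode not in ("common", "shrunk", "trended"):
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")
    samples_a = sheet.samples_in_group(group_a)
    samples_b = sheet.samples_in_group(group_b)
    if not samples_a:
        raise ValueError(f"group {group_a!r} absent from sample sheet")
    if not samples_b:
        raise ValueError(f"group {group_b!r} absent from sample sheet")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need >= 2 samples for the exact test")

    sub = counts.subset_samples(samples_a + samples_b)
    norm = tmm_factors(sub)
    pseudo = _equalize_libraries(sub.counts.astype(float), norm.effective_sizes)
    n_a, n_b = len(samples_a), len(samples_b)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n_a + n_b)

    if dispersion_mode == "common":
        phi = np.full(sub.n_genes, _mom_common_dispersion(pseudo, [idx_a, idx_b]))
    elif dispersion_mode == "trended":
        phi = _mom_trended_dispersion(pseudo, [idx_a, idx_b])
    else:  # shrunk: gene-wise estimates pulled toward the trend
        trend = _mom_trended_dispersion(pseudo, [idx_a, idx_b])
        genewise = _mom_genewise_dispersion(pseudo, [idx_a, idx_b])
        resid_df = n_a + n_b - 2
        phi = (prior_df * trend + resid_df * genewise) / (prior_df + resid_df)

    mean_a = pseudo[:, idx_a].mean(axis=1)
    mean_b = pseudo[:, idx_b].mean(axis=1)
    log2fc = np.log2(mean_b + prior_count) - np.log2(mean_a + prior_count)

    p = np.empty(sub.n_genes)
    sums_a = pseudo[:, idx_a].sum(axis=1)
    sums_b = pseudo[:, idx_b].sum(axis=1)
    for g in range(sub.n_genes):
        p[g] = exact_nb_pvalue(sums_a[g], sums_b[g], n_a, n_b, phi[g])

    fdr = bh_adjust(p)
    rank_score = signed_inverse_p_rank(log2fc, p)
    table = pd.DataFrame(
        {
            "mean_count": pseudo.mean(axis=1),
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
            "rank_score": rank_score,
        },
        index=pd.Index(sub.gene_ids, name="gene_id"),
    )
    return ContrastResult(group_a, group_b, table)


# ---------------------------------------------------------------------------
# cross-contrast comparison and reporting helpers
# ---------------------------------------------------------------------------


def compare_contrasts(
    result_a: ContrastResult,
    result_b: ContrastResult,
    threshold: float = 0.05,
    n_bins: int = 50,
) -> dict:
    """Venn counts, rank-rank 2D histogram and Spearman correlation.

    Returns a dict with ``unique_a``/``unique_b``/``shared`` counts of
    FDR-significant genes, per-class gene id lists, the ``n_bins`` x
    ``n_bins`` histogram of rank-score ranks, and ``spearman``.
    """
    common = [g for g in result_a.table.index if g in set(result_b.table.index)]
    if not common:
        raise ValueError("contrasts share no genes")
    ta = result_a.table.loc[common]
    tb = result_b.table.loc[common]
    sig_a = set(ta.index[ta["fdr"] < threshold])
    sig_b = set(tb.index[tb["fdr"] < threshold])
    ranks_a = stats.rankdata(ta["rank_score"])
    ranks_b = stats.rankdata(tb["rank_score"])
    hist, _, _ = np.histogram2d(ranks_a, ranks_b, bins=n_bins)
    rho = stats.spearmanr(ta["rank_score"], tb["rank_score"]).statistic
    return {
        "unique_a": len(sig_a - sig_b),
        "unique_b": len(sig_b - sig_a),
        "shared": len(sig_a & sig_b),
        "shared_genes": sorted(sig_a & sig_b),
        "unique_a_genes": sorted(sig_a - sig_b),
        "unique_b_genes": sorted(sig_b - sig_a),
        "rank_rank_hist": hist,
        "spearman": float(rho),
        "n_genes": len(common),
    }


def pca_coordinates(
    counts: CountMatrix,
    n_top: int = 500,
    n_components: int = 2,
) -> pd.DataFrame:
    """Sample PCA of log2-CPM on the most variable genes (reporting aid)."""
    y = counts.counts.astype(float)
    lib = y.sum(axis=0)
    cpm = np.log2(y / lib[None, :] * 1e6 + 1.0)
    var = cpm.var(axis=1)
    top = np.argsort(var)[::-1][: min(n_top, counts.n_genes)]
    x = cpm[top].T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    frame = pd.DataFrame(
        coords,
        index=pd.Index(counts.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    total = (s**2).sum()
    frame.attrs["explained_fraction"] = [float(si**2 / total) for si in s[:k]]
    return frame
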