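"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the design of a 2x2 (age x DOCA-hypertension)
mouse heart RNA-seq study: four groups with sizes young-sham 6 and 4 in
each of young-DOCA, aging-sham and aging-DOCA; negative-binomial counts
with a mean-dependent dispersion; differential-expression effects on
the treatment factor within each age stratum; and coherently shifted
gene sets that mimic activated pathways. The default test scale is
2,000 genes and 100 sets, small enough for calibration experiments yet
structured like the full ~14,000-gene post-filter matrix.

Counts for gene g in sample s are drawn as

    counts ~ NB(mu_gs, phi_g),
    log2 mu_gs = baseline_g + log2_libsize_s + effects_gs,
    phi_g = phi0 + slope / mu_g    (dispersion, var = mu + phi mu^2)

A single integer seed drives all draws through deterministically
spawned sub-streams, so identical configurations are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from gscontrast.io import (
    CountMatrix,
    GeneSetCollection,
    SampleSheet,
    SummaryStatsTable,
)
import pandas as pd


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


GROUPS = ("young-sham", "young-DOCA", "aging-sham", "aging-DOCA")
CONTRASTS = ("young", "aging")  # sham vs DOCA within each age stratum


@dataclass
class SimulationConfig:
    """Parameters of the count simulator.

    Defaults mirror the study design: group sizes (6, 4, 4, 4), a
    log2-normal baseline expression distribution, NB dispersion
    phi = phi0 + slope/mu, 5% DE genes per contrast at |log2FC| = 2,
    and three coherently activated sets per contrast shifted by one
    log2 unit in the DOCA samples of that age stratum.
    """

    n_genes: int = 2000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "young-sham": 6,
            "young-DOCA": 4,
            "aging-sham": 4,
            "aging-DOCA": 4,
        }
    )
    baseline_log_mean: tuple[float, float] = (5.0, 2.0)  # log2 scale
    dispersion_model: tuple[float, float] = (0.05, 2.0)  # phi0, slope
    library_size_log2_sd: float = 0.25
    de_fraction: float = 0.05
    de_log2fc_magnitude: float = 2.0
    age_effect_log2_sd: float = 0.1
    n_active_sets: int = 3
    set_shift_delta: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for g in GROUPS:
            if g not in self.group_sizes:
                raise ConfigError(f"missing group size for {g!r}")
            if self.group_sizes[g] < 2:
                raise ConfigError(f"group {g!r} must have >= 2 samples")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigError("de_fraction must be in [0, 1]")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_active_sets < 0:
            raise ConfigError("n_active_sets must be >= 0")


@dataclass
class GroundTruth:
    """Planted effects, sufficient to score recovery of every stage.

    ``de_genes`` maps contrast ("young"/"aging") to {gene id: true
    log2FC of DOCA over sham}; ``active_sets`` maps contrast to
    {set name: +1 (up in DOCA) or -1 (down)}; ``phenotype_means``
    holds true cell means for simulated phenotype endpoints.
    """

    de_genes: dict[str, dict[str, float]]
    active_sets: dict[str, dict[str, int]]
    phenotype_means: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_random_collection(
    n_sets: int,
    size_range: tuple[int, int],
    universe: Sequence[str],
    seed: int,
    prefix: str = "SET",
) -> GeneSetCollection:
    """Sample gene sets uniformly without replacement from ``universe``."""
    if n_sets <= 0:
        raise ConfigError("n_sets must be positive")
    lo, hi = size_range
    if lo < 2 or hi > len(universe) or lo > hi:
        raise ConfigError(
            f"size_range {size_range} must lie within [2, {len(universe)}]"
        )
    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets: dict[str, list[str]] = {}
    width = len(str(n_sets))
    for i in range(n_sets):
        k = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=k, replace=False)
        sets[f"{prefix}{i + 1:0{width}d}"] = [universe[j] for j in sorted(members)]
    return GeneSetCollection(sets, {name: "simulated" for name in sets})


def simulate_counts(
    config: SimulationConfig,
    collection: GeneSetCollection | None = None,
) -> tuple[CountMatrix, SampleSheet, GroundTruth]:
    """Draw a NB count matrix with planted DE genes and activated sets.

    DE effects act on the treatment factor within each age stratum
    (half up, half down at ``de_log2fc_magnitude``). For each contrast,
    ``n_active_sets`` sets from ``collection`` additionally receive a
    coherent member-wise shift of ``set_shift_delta`` log2 units in the
    DOCA samples of that stratum. Returns the matrix, a matching sample
    sheet and the full ground truth.
    """
    config.validate()
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    if collection is not None:
        unknown = {g for ms in collection.sets.values() for g in ms} - set(gene_ids)
        if unknown:
            raise ConfigError(
                f"collection members outside the simulated gene universe: "
                f"{sorted(unknown)[:5]}"
            )

    rng_base, rng_lib, rng_de, rng_sets, rng_counts, rng_age = _spawn(config.seed, 6)

    # samples, ordered by group
    sample_ids: list[str] = []
    group_of: list[str] = []
    for group in GROUPS:
        for r in range(config.group_sizes[group]):
            sample_ids.append(f"{group}-{r + 1}")
            group_of.append(group)
    n_samples = len(sample_ids)
    age_of = np.array([g.split("-")[0] for g in group_of])
    trt_of = np.array([g.split("-")[1] for g in group_of])

    baseline = rng_base.normal(*config.baseline_log_mean, size=config.n_genes)
    lib = rng_lib.normal(0.0, config.library_size_log2_sd, size=n_samples)
    # mild age main effect on a random subset so the factorial structure exists
    age_eff = np.zeros(config.n_genes)
    age_idx = rng_age.choice(
        config.n_genes, size=max(1, config.n_genes // 10), replace=False
    )
    age_eff[age_idx] = rng_age.normal(0.0, config.age_effect_log2_sd, size=len(age_idx))

    effects = np.zeros((config.n_genes, n_samples))

    # coherently activated sets, chosen first so their members can be
    # withheld from the DE-gene draw: ground truth stays attributable
    # (a "young-activated" set carries no incidental aging DE genes)
    active_sets: dict[str, dict[str, int]] = {c: {} for c in CONTRASTS}
    active_members: set[int] = set()
    if collection is not None and config.n_active_sets > 0:
        names = list(collection.names)
        if len(names) < 2 * config.n_active_sets:
            raise ConfigError("collection too small for the requested active sets")
        chosen = rng_sets.choice(
            len(names), size=2 * config.n_active_sets, replace=False
        )
        pos = {g: i for i, g in enumerate(gene_ids)}
        for slot, name_i in enumerate(chosen):
            contrast = CONTRASTS[slot % 2]
            name = names[name_i]
            members = collection[name]
            if not members:
                raise ConfigError(f"set {name!r} has no genes in the universe")
            direction = 1 if rng_sets.random() < 0.5 else -1
            active_sets[contrast][name] = direction
            in_stratum_doca = (age_of == contrast) & (trt_of == "DOCA")
            midx = [pos[g] for g in members]
            active_members.update(midx)
            effects[np.ix_(midx, in_stratum_doca)] += direction * config.set_shift_delta

    # planted DE genes per contrast (treatment effect within the stratum)
    de_genes: dict[str, dict[str, float]] = {c: {} for c in CONTRASTS}
    n_de = int(round(config.de_fraction * config.n_genes))
    free = np.array(
        [i for i in range(config.n_genes) if i not in active_members], dtype=int
    )
    if n_de > len(free):
        raise ConfigError("de_fraction too high for the non-set gene pool")
    for contrast in CONTRASTS:
        idx = free[rng_de.choice(len(free), size=n_de, replace=False)]
        signs = rng_de.choice([-1.0, 1.0], size=n_de)
        in_stratum_doca = (age_of == contrast) & (trt_of == "DOCA")
        for i, s in zip(idx, signs):
            lfc = s * config.de_log2fc_magnitude
            de_genes[contrast][gene_ids[i]] = lfc
            effects[i, in_stratum_doca] += lfc

    log2_mu = baseline[:, None] + lib[None, :] + effects
    log2_mu += np.where(age_of == "aging", age_eff[:, None], 0.0)
    mu = np.exp2(log2_mu)
    phi0, slope = config.dispersion_model
    phi = phi0 + slope / np.maximum(mu.mean(axis=1), 1e-8)
    phi = np.maximum(phi, 1e-8)[:, None]
    # NB as gamma-Poisson: shape 1/phi, scale mu*phi
    lam = rng_counts.gamma(shape=1.0 / phi, scale=mu * phi)
    counts = rng_counts.poisson(lam).astype(np.int64)

    matrix = CountMatrix(gene_ids, sample_ids, counts)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "age_group": age_of,
                "treatment": trt_of,
            }
        )
    )
    truth = GroundTruth(de_genes=de_genes, active_sets=active_sets)
    return matrix, sheet, truth


def simulate_phenotype_summaries(
    true_cell_means: dict[str, dict[str, float]],
    true_sd: float,
    group_sizes: dict[str, int],
    seed: int,
) -> SummaryStatsTable:
    """Draw per-animal values and summarize each cell as mean/SEM/n.

    Emulates a printed phenotype table: for each endpoint and group,
    ``n`` normal draws around the true cell mean with common SD
    ``true_sd``; the cell reports the sample mean, SEM = sd_hat/sqrt(n)
    and n.
    """
    if not true_sd > 0:
        raise ConfigError("true_sd must be > 0")
    for g, n in group_sizes.items():
        if n < 2:
            raise ConfigError(f"group {g!r} must have n >= 2")
    rng = np.random.default_rng(seed)
    cells: dict[str, dict[str, tuple[float, float, int]]] = {}
    for endpoint, means in true_cell_means.items():
        cells[endpoint] = {}
        for group, mu in means.items():
            n = group_sizes[group]
            draws = rng.normal(mu, true_sd, size=n)
            sem = draws.std(ddof=1) / np.sqrt(n)
            cells[endpoint][group] = (float(draws.mean()), float(max(sem, 1e-12)), n)
    return SummaryStatsTable(cells)
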