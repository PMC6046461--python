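"""End-to-end pipeline driver for the 2x2 contrast study.

Orchestrates the full reanalysis on either simulated or file-based
inputs: low-count filtering, per-contrast NB differential expression
(sham vs DOCA within each age stratum), signed inverse-p ranking,
pre-ranked 1D enrichment, Gsheat set scoring with differential set
testing, 2D multi-contrast enrichment with quadrant classification,
cross-contrast Venn/rank-rank comparison and PCA coordinates. Every
stage writes plain TSV into the output directory, and a manifest
records the configuration hash and per-stage output checksums so that
a rerun with the same configuration and seed is verifiably identical.

A single global seed is fanned out per stage through deterministically
spawned sub-seeds, so stages can be re-run in isolation from their
predecessors' TSVs without changing results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gscontrast import diffexpr, enrich1d, gsheat, multicontrast
from gscontrast.io import (
    CountMatrix,
    GeneSetCollection,
    SampleSheet,
    read_counts,
    read_gmt,
    read_sample_sheet,
    write_counts,
    write_gmt,
    write_results_table,
)
from gscontrast.simulate import SimulationConfig, simulate_counts, simulate_random_collection

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``counts_path``/``samples_path``/``gmt_path`` are given, or
    ``simulate`` is true and the synthetic dataset is generated from
    ``sim`` (the generator's own defaults emulate the study design:
    groups 6/4/4/4, 2,000 genes; 100 random sets are drawn when no GMT
    is supplied). The two contrasts are sham vs DOCA within the young
    and aging strata.
    """

    out_dir: str = "gscontrast_run"
    simulate: bool = True
    counts_path: str | None = None
    samples_path: str | None = None
    gmt_path: str | None = None
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_sim_sets: int = 100
    sim_set_sizes: tuple[int, int] = (10, 50)
    contrasts: tuple[tuple[str, str], ...] = (
        ("young-sham", "young-DOCA"),
        ("aging-sham", "aging-DOCA"),
    )
    min_mean: float = 10.0
    de_fdr: float = 0.05
    gsea_fdr: float = 0.05
    n_perm: int = 1000
    enrich_min_size: int = 10
    enrich_max_size: int = 500
    method_2d: str = "hotelling"
    n_top_heatmap: int = 50
    seed: int = 0

    def validate(self) -> None:
        if len(self.contrasts) != 2:
            raise ValueError("exactly two contrasts are required for the 2D stage")
        for thr in (self.de_fdr, self.gsea_fdr):
            if not 0 < thr < 1:
                raise ValueError(f"FDR threshold {thr} outside (0, 1)")
        if self.min_mean < 0:
            raise ValueError("min_mean must be >= 0")
        if not self.simulate:
            for p, what in (
                (self.counts_path, "counts_path"),
                (self.samples_path, "samples_path"),
                (self.gmt_path, "gmt_path"),
            ):
                if p is None:
                    raise ValueError(f"{what} required when simulate is false")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = SimulationConfig(**sim_raw)
        if "contrasts" in raw:
            cfg.contrasts = tuple(tuple(c) for c in raw["contrasts"])
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # where results land is not what they are
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    seed: int
    stage_seconds: dict[str, float]
    checksums: dict[str, str]
    counts: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True), encoding="utf-8"
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(
    config: PipelineConfig, seeds: list[int]
) -> tuple[CountMatrix, SampleSheet, GeneSetCollection, dict | None]:
    if config.simulate:
        sim = SimulationConfig(**{**asdict(config.sim), "seed": seeds[0]})
        universe = [f"G{i + 1:05d}" for i in range(sim.n_genes)]
        collection = simulate_random_collection(
            config.n_sim_sets, config.sim_set_sizes, universe, seed=seeds[1]
        )
        counts, sheet, truth = simulate_counts(sim, collection)
        return counts, sheet, collection, truth.to_dict()
    counts = read_counts(config.counts_path)
    sheet = read_sample_sheet(config.samples_path)
    sheet.validate_against(counts)
    collection = read_gmt(config.gmt_path)
    return counts, sheet, collection, None


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(config.seed).spawn(8)]
    times: dict[str, float] = {}
    fun_counts: dict[str, int] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                times[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done in %.2fs", name, times[name])

        return _Timer()

    with stage("inputs"):
        counts, sheet, collection, truth = _load_inputs(config, seeds)
        write_counts(counts, out / "counts.tsv")
        sheet.table.to_csv(out / "samples.tsv", sep="\t", index=False)
        write_gmt(collection, out / "sets.gmt")
        if truth is not None:
            (out / "ground_truth.json").write_text(
                json.dumps(truth, indent=2, sort_keys=True), encoding="utf-8"
            )
        fun_counts["genes_input"] = counts.n_genes

    with stage("filter"):
        filtered = diffexpr.filter_low_counts(counts, config.min_mean)
        fun_counts["genes_after_filter"] = filtered.n_genes
        logger.info(
            "filter funnel: %d genes -> %d after min mean %g",
            counts.n_genes,
            filtered.n_genes,
            config.min_mean,
        )

    results: list[diffexpr.ContrastResult] = []
    with stage("diffexpr"):
        for i, (ga, gb) in enumerate(config.contrasts, start=1):
            res = diffexpr.nb_exact_contrast(filtered, sheet, ga, gb)
            results.append(res)
            tab = res.table.reset_index()
            write_results_table(tab, out / f"contrast{i}_de.tsv")
            fun_counts[f"de_genes_contrast{i}"] = int(
                (res.table["fdr"] < config.de_fdr).sum()
            )
        pca = diffexpr.pca_coordinates(filtered)
        write_results_table(pca.reset_index(), out / "pca_coordinates.tsv")

    with stage("compare"):
        cmp = diffexpr.compare_contrasts(results[0], results[1], config.de_fdr)
        fun_counts["de_shared"] = cmp["shared"]
        fun_counts["de_unique_contrast1"] = cmp["unique_a"]
        fun_counts["de_unique_contrast2"] = cmp["unique_b"]
        venn = pd.DataFrame(
            [
                {"class": "unique_contrast1", "count": cmp["unique_a"]},
                {"class": "unique_contrast2", "count": cmp["unique_b"]},
                {"class": "shared", "count": cmp["shared"]},
            ]
        )
        write_results_table(venn, out / "venn_counts.tsv")
        np.savetxt(out / "rank_rank_hist.tsv", cmp["rank_rank_hist"], fmt="%d", delimiter="\t")

    with stage("enrich1d"):
        for i, res in enumerate(results, start=1):
            ranked = enrich1d.RankedList.from_series(res.ranked_gene_list())
            enr = enrich1d.permutation_enrichment(
                ranked,
                collection,
                n_perm=config.n_perm,
                seed=seeds[2] + i,
                min_size=config.enrich_min_size,
                max_size=config.enrich_max_size,
            )
            write_results_table(
                enr.table.reset_index().sort_values(["fdr", "nes"], key=None),
                out / f"contrast{i}_enrichment1d.tsv",
            )
            fun_counts[f"enriched_sets_contrast{i}"] = int(
                (enr.table["fdr"] < config.gsea_fdr).sum()
            )

    with stage("gsheat"):
        scores = gsheat.set_score_matrix(filtered, collection)
        write_results_table(
            scores.to_frame().reset_index(names="set_name"), out / "gsheat_scores.tsv"
        )
        diff_sets = []
        for i, (ga, gb) in enumerate(config.contrasts, start=1):
            d = gsheat.differential_sets(scores, sheet, ga, gb)
            diff_sets.append(d)
            write_results_table(
                d.table.reset_index(), out / f"contrast{i}_gsheat_diff.tsv"
            )
            fun_counts[f"gsheat_sets_contrast{i}"] = int(
                (d.table["fdr"] < config.gsea_fdr).sum()
            )
        n_top = min(config.n_top_heatmap, len(diff_sets[0].table))
        ordered = gsheat.top_sets_heatmap(
            scores, diff_sets[0], n_top, figure_path=out / "gsheat_heatmap.svg"
        )
        write_results_table(ordered.reset_index(names="set_name"), out / "gsheat_heatmap_matrix.tsv")
        gsheat.export_enrichment_map(
            diff_sets[0],
            collection,
            fdr_cut=config.gsea_fdr,
            node_path=out / "enrichment_map_nodes.tsv",
            edge_path=out / "enrichment_map_edges.tsv",
        )

    with stage("multicontrast"):
        table = multicontrast.joint_ranks(results[0], results[1])
        write_results_table(table.to_frame().reset_index(), out / "joint_ranks.tsv")
        enr2d = multicontrast.significance_2d(
            table,
            collection,
            method=config.method_2d,
            n_perm=config.n_perm,
            seed=seeds[3],
            min_size=config.enrich_min_size,
        )
        classified = multicontrast.classify_quadrants(enr2d, fdr_cut=config.gsea_fdr)
        write_results_table(classified.reset_index(), out / "enrichment2d.tsv")
        class_counts = classified.attrs["class_counts"]
        write_results_table(
            pd.DataFrame(
                [{"class": k, "count": v} for k, v in sorted(class_counts.items())]
            ),
            out / "quadrant_report.tsv",
        )
        for k, v in class_counts.items():
            fun_counts[f"sets_{k}"] = int(v)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        stage_seconds=times,
        checksums={
            p.name: _sha256(p)
            for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.gmt")) + sorted(out.glob("ground_truth.json"))
        },
        counts=fun_counts,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def make_report(out_dir: str | Path) -> str:
    """Summarize a completed run as markdown (written to report.md).

    Missing stage outputs are listed as absent rather than fatal, so a
    partial run still produces a readable report.
    """
    out = Path(out_dir)
    lines = ["# Pipeline run report", ""]
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
        lines += [
            f"- configuration hash: `{manifest['config_hash']}`",
            f"- seed: {manifest['seed']}",
            "",
        ]
        lines.append("## Stage counts")
        for k, v in sorted(manifest["counts"].items()):
            lines.append(f"- {k}: {v}")
        lines.append("")
    else:
        lines.append("- manifest.json: ABSENT")

    expected = {
        "differential expression (contrast 1)": "contrast1_de.tsv",
        "differential expression (contrast 2)": "contrast2_de.tsv",
        "Venn counts": "venn_counts.tsv",
        "1D enrichment (contrast 1)": "contrast1_enrichment1d.tsv",
        "1D enrichment (contrast 2)": "contrast2_enrichment1d.tsv",
        "Gsheat scores": "gsheat_scores.tsv",
        "Gsheat differential sets (contrast 1)": "contrast1_gsheat_diff.tsv",
        "2D enrichment": "enrichment2d.tsv",
        "quadrant report": "quadrant_report.tsv",
    }
    lines.append("## Stage outputs")
    for label, fname in expected.items():
        path = out / fname
        if not path.exists():
            lines.append(f"- {label}: ABSENT ({fname})")
            continue
        frame = pd.read_csv(path, sep="\t")
        lines.append(f"- {label}: {len(frame)} rows ({fname})")
        if fname == "venn_counts.tsv":
            for _, row in frame.iterrows():
                lines.append(f"    - {row['class']}: {row['count']}")
        if fname == "quadrant_report.tsv":
            for _, row in frame.iterrows():
                lines.append(f"    - {row['class']}: {row['count']}")
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text, encoding="utf-8")
    return text
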