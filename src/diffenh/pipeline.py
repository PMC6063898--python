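"""End-to-end orchestration: simulate/load → catalog → cluster → link.

``run_pipeline`` drives the full differential enhancer-activation
analysis and writes every artifact (catalog BED, signal and ratio
matrices, activated-group BED, ranked nearest-gene table, metaprofiles,
run manifest) into an output directory.  Inputs come either from a
synthetic scenario or from files on disk (bedGraph tracks, annotation
TSV, per-condition gene-count TSVs).  All randomness flows from the
single configured seed, so a fixed config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    Metaprofile,
    StateRatioMatrix,
    compute_ratio_matrix,
    kmeans_cluster,
    metaprofile,
    metaprofile_frame,
    select_activated_group,
)
from .genome import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    read_annotation,
    read_bedgraph,
    rpkm_normalize,
    write_annotation,
    write_bed,
    write_bedgraph,
)
from .linkage import (
    adjust_bh,
    de_significance,
    expression_fold_change,
    link_enhancers,
    rank_group_genes,
)
from .peaks import EnhancerCatalog, call_peaks, merge_close_peaks, select_putative_enhancers
from .simulate import (
    GroundTruth,
    ScenarioConfig,
    make_genome,
    simulate_mark_tracks,
    simulate_rnaseq,
    write_ground_truth,
)

log = logging.getLogger("diffenh")


class ConfigError(ValueError):
    """Raised for an invalid or contradictory pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated parameters of a pipeline run.

    Defaults follow the analysis conventions: peak p-value cutoff
    0.001, peaks merged below a 500 bp gap, 2 kb TSS exclusion for
    distal-enhancer selection, 0.5 RPKM ratio pseudocount, k = 4
    clusters, top 10 ranked genes.
    """

    outdir: str = "diffenh_out"
    scenario: ScenarioConfig | None = None
    # file inputs (used when scenario is None)
    annotation: str | None = None
    tracks: dict[str, str] = field(default_factory=dict)  # "MARK_COND" -> bedGraph
    counts_a: str | None = None
    counts_b: str | None = None
    # analysis parameters
    p_cutoff: float = 0.001
    merge_gap: int = 500
    tss_exclusion: int = 2_000
    pseudocount: float = 0.5
    k: int = 4
    seed: int = 0
    top_n: int = 10
    metaprofile_window: int = 5_000


def validate_config(raw: "dict | PipelineConfig") -> PipelineConfig:
    """Normalize a raw dict (e.g. parsed YAML) into a PipelineConfig.

    Fills defaults, builds the nested scenario config, and aggregates
    every violation into one error message.
    """
    if isinstance(raw, PipelineConfig):
        cfg = raw
    else:
        raw = dict(raw)
        scenario = raw.pop("scenario", None)
        if isinstance(scenario, dict):
            try:
                scenario = ScenarioConfig(**scenario)
            except TypeError as exc:
                raise ConfigError(f"bad scenario config: {exc}") from exc
        known = {f for f in PipelineConfig.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = PipelineConfig(scenario=scenario, **raw)

    if cfg.scenario is None and not (cfg.annotation or cfg.tracks or cfg.counts_a or cfg.counts_b):
        # an empty config means the default synthetic scenario
        cfg.scenario = ScenarioConfig(seed=cfg.seed)

    problems: list[str] = []
    if cfg.p_cutoff <= 0 or cfg.p_cutoff >= 1:
        problems.append("p_cutoff must be in (0, 1)")
    if cfg.merge_gap < 0:
        problems.append("merge_gap must be >= 0")
    if cfg.tss_exclusion < 0:
        problems.append("tss_exclusion must be >= 0")
    if cfg.pseudocount <= 0:
        problems.append("pseudocount must be positive")
    if cfg.k < 2:
        problems.append("k must be >= 2 (clustering needs at least two groups)")
    if cfg.top_n < 1:
        problems.append("top_n must be >= 1")
    if cfg.scenario is None:
        if not cfg.annotation:
            problems.append("either a scenario or an annotation path is required")
        needed = {"H3K4me1_A", "H3K4me1_B", "H3K27ac_A", "H3K27ac_B"}
        missing = needed - set(cfg.tracks)
        if missing and not cfg.scenario:
            problems.append(f"missing track inputs: {sorted(missing)}")
        for key, path in cfg.tracks.items():
            if not Path(path).exists():
                problems.append(f"track file for {key} not found: {path}")
        if cfg.annotation and not Path(cfg.annotation).exists():
            problems.append(f"annotation file not found: {cfg.annotation}")
        for label, path in (("counts_a", cfg.counts_a), ("counts_b", cfg.counts_b)):
            if path and not Path(path).exists():
                problems.append(f"{label} file not found: {path}")
    else:
        try:
            cfg.scenario.validate()
        except ValueError as exc:
            problems.append(f"scenario: {exc}")
    if problems:
        raise ConfigError("; ".join(problems))
    return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    catalog: EnhancerCatalog
    matrix: StateRatioMatrix
    activated_group: set[str]
    links: pd.DataFrame
    ranked_table: pd.DataFrame
    metaprofiles: dict[str, Metaprofile]
    truth: GroundTruth | None
    paths: dict[str, str]


def _read_counts(path: str) -> pd.Series:
    table = pd.read_csv(path, sep="\t")
    if "gene_id" not in table.columns or "count" not in table.columns:
        raise ConfigError(f"{path}: expected columns gene_id and count")
    return table.set_index("gene_id")["count"]


def run_pipeline(config: "dict | PipelineConfig") -> PipelineResult:
    """Run the full analysis and write all artifacts under ``outdir``."""
    cfg = validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    truth: GroundTruth | None = None

    # ----- inputs -----
    if cfg.scenario is not None:
        log.info("simulating scenario (seed=%d)", cfg.scenario.seed)
        truth = make_genome(cfg.scenario)
        tracks_raw = simulate_mark_tracks(truth, cfg.scenario)
        counts_a, counts_b = simulate_rnaseq(truth, cfg.scenario)
        genes = truth.genes
        inputs_dir = outdir / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        write_annotation(genes, inputs_dir / "genes.tsv")
        write_ground_truth(truth, inputs_dir / "ground_truth.json")
        for (mark, cond), track in tracks_raw.items():
            write_bedgraph(track, inputs_dir / f"{mark}_{cond}.bedgraph")
        for label, series in (("A", counts_a), ("B", counts_b)):
            series.rename("count").to_csv(inputs_dir / f"counts_{label}.tsv", sep="\t")
        paths["inputs"] = str(inputs_dir)
    else:
        genes = read_annotation(cfg.annotation)
        tracks_raw = {}
        for key, path in cfg.tracks.items():
            mark, _, cond = key.rpartition("_")
            tracks_raw[(mark, cond)] = read_bedgraph(path)
        counts_a = _read_counts(cfg.counts_a) if cfg.counts_a else None
        counts_b = _read_counts(cfg.counts_b) if cfg.counts_b else None

    # ----- catalog -----
    catalog = build_catalog(tracks_raw, genes, cfg)
    log.info("catalog: %d merged putative enhancers", len(catalog))
    write_bed(catalog.intervals, outdir / "catalog.bed")
    catalog.signal.to_csv(outdir / "catalog_signal.tsv", sep="\t")
    paths["catalog_bed"] = str(outdir / "catalog.bed")
    paths["catalog_signal"] = str(outdir / "catalog_signal.tsv")

    # ----- clustering -----
    matrix = compute_ratio_matrix(catalog, "A", "B", cfg.pseudocount)
    matrix = kmeans_cluster(matrix, k=cfg.k, seed=cfg.seed)
    group = select_activated_group(matrix)
    log.info("clustered %d rows into k=%d; activated group has %d enhancers",
             len(matrix), cfg.k, len(group))
    ratio_out = matrix.values.copy()
    ratio_out["cluster"] = matrix.labels
    ratio_out["activated"] = [i in group for i in matrix.ids]
    ratio_out.to_csv(outdir / "ratio_matrix.tsv", sep="\t")
    group_intervals = [iv for iv in catalog.intervals if iv.name in group]
    write_bed(group_intervals, outdir / "activated_group.bed")
    paths["ratio_matrix"] = str(outdir / "ratio_matrix.tsv")
    paths["activated_group_bed"] = str(outdir / "activated_group.bed")

    # ----- gene linkage -----
    links = link_enhancers(catalog.intervals, genes)
    if counts_a is not None and counts_b is not None:
        fc = expression_fold_change(counts_a, counts_b)
        pvals = de_significance(counts_a, counts_b)
        adj = adjust_bh(pvals)
        ranked = rank_group_genes(group, links, fc, pvals, adj, top_n=cfg.top_n)
    else:
        ranked = pd.DataFrame()
    links.to_csv(outdir / "enhancer_gene_links.tsv", sep="\t", index=False)
    ranked.to_csv(outdir / "ranked_genes.tsv", sep="\t", index=False)
    paths["links"] = str(outdir / "enhancer_gene_links.tsv")
    paths["ranked_genes"] = str(outdir / "ranked_genes.tsv")

    # ----- metaprofiles -----
    profiles: dict[str, Metaprofile] = {}
    if catalog.intervals:
        for mark in ("H3K4me1", "H3K27ac"):
            for cond in ("A", "B"):
                if (mark, cond) in tracks_raw:
                    rpkm = rpkm_normalize(tracks_raw[(mark, cond)])
                    profiles[f"{mark}_{cond}_center"] = metaprofile(
                        rpkm, catalog.intervals, "center_anchored", cfg.metaprofile_window
                    )
    for cond in ("A", "B"):
        if ("H3K4me3", cond) in tracks_raw and genes:
            rpkm = rpkm_normalize(tracks_raw[("H3K4me3", cond)])
            profiles[f"H3K4me3_{cond}_tss"] = metaprofile(
                rpkm, genes, "tss_anchored", cfg.metaprofile_window
            )
    for name, prof in profiles.items():
        metaprofile_frame(prof).to_csv(outdir / f"metaprofile_{name}.tsv", sep="\t", index=False)
    paths["metaprofiles"] = str(outdir)

    # ----- manifest -----
    manifest = {
        "diffenh_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": _config_dict(cfg),
        "n_catalog": len(catalog),
        "n_clustered": len(matrix),
        "n_activated_group": len(group),
        "n_genes": len(genes),
        "n_ranked": len(ranked),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    paths["manifest"] = str(outdir / "manifest.json")

    return PipelineResult(
        config=cfg,
        catalog=catalog,
        matrix=matrix,
        activated_group=group,
        links=links,
        ranked_table=ranked,
        metaprofiles=profiles,
        truth=truth,
        paths=paths,
    )


def build_catalog(
    tracks_raw: dict[tuple[str, str], CoverageTrack],
    genes: list[GeneModel],
    cfg: PipelineConfig,
) -> EnhancerCatalog:
    """Peak-call → select distal H3K4me1 regions → merge → attach signal."""
    from .peaks import attach_signal  # local import keeps module surface tidy

    def peaks_for(mark: str, cond: str) -> list[GenomicInterval]:
        key = (mark, cond)
        if key not in tracks_raw:
            return []
        return call_peaks(tracks_raw[key], p_cutoff=cfg.p_cutoff).intervals()

    k4me1_a = peaks_for("H3K4me1", "A")
    k4me1_b = peaks_for("H3K4me1", "B")
    k4me3 = peaks_for("H3K4me3", "A") + peaks_for("H3K4me3", "B")
    selected = select_putative_enhancers(
        k4me1_a, k4me1_b, k4me3, genes, tss_exclusion=cfg.tss_exclusion
    )
    merged = merge_close_peaks(selected, max_gap=cfg.merge_gap)
    ratio_tracks = {
        (mark, cond): rpkm_normalize(tracks_raw[(mark, cond)])
        for mark in ("H3K4me1", "H3K27ac")
        for cond in ("A", "B")
        if (mark, cond) in tracks_raw
    }
    return attach_signal(merged, ratio_tracks)


def _config_dict(cfg: PipelineConfig) -> dict:
    out = asdict(cfg)
    out.pop("outdir", None)  # analysis is outdir-independent
    if cfg.scenario is not None:
        out["scenario"] = asdict(cfg.scenario)
    return out
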