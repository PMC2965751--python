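"""Config-driven end-to-end run: (simulate | ingest) -> normalize ->
summarize -> cluster -> metagene -> trend.

A single declarative YAML config names the inputs and surfaces every
analysis constant (promoter cap 250 bp, minimum gene length 500 bp,
metagene bin 50 bp / span 300 bp, trend window 300 genes) as a key with
its conventional default.  Outputs are plain TSV plus a JSON run manifest
(config echo, seed, package version); identical config and seed reproduce
byte-identical tables.  If any stage fails, a ``FAILED`` marker naming the
error is left in the output directory so partial output is never mistaken
for a completed run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .cluster_trend import feature_matrix, sliding_median_trend, som_fit
from .metagene import MetageneConfig, aggregate_profile, smooth_profile
from .normalize import load_manifest, process_manifest
from .summarize import (
    MIN_GENE_LENGTH,
    PROMOTER_CAP,
    GeneSummaryTable,
    filter_genes,
)
from .synthetic import SimulationConfig, make_fixture, write_fixture
from .tracks_io import ValidationError, read_annotation, write_track

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("chiptile")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring)."""

    output_dir: Path
    seed: int = 0
    # input: either a simulation block or annotation+manifest paths
    simulate: dict[str, Any] | None = None
    annotation: Path | None = None
    annotation_format: str | None = None
    manifest: Path | None = None
    # stage options
    center: bool = True
    robust: bool = False
    promoter_cap: int = PROMOTER_CAP
    min_gene_length: int = MIN_GENE_LENGTH
    cluster_k: int | None = None
    cluster_experiments: list[str] = field(default_factory=list)
    cluster_regions: list[str] = field(default_factory=lambda: ["promoter", "orf"])
    cluster_epochs: int = 100
    metagene_bin: int = 50
    metagene_span: int = 300
    metagene_extent: int = 500
    metagene_stat: str = "mean"
    trend_window: int = 300
    trend_x: str | None = None  # "experiment:region"
    trend_y: str | None = None

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any]) -> "PipelineConfig":
        cluster = cfg.get("cluster") or {}
        mg = cfg.get("metagene") or {}
        trend = cfg.get("trend") or {}
        norm = cfg.get("normalize") or {}
        summ = cfg.get("summarize") or {}
        inp = cfg.get("input") or {}
        return cls(
            output_dir=Path(cfg["output_dir"]),
            seed=int(cfg.get("seed", 0)),
            simulate=cfg.get("simulate"),
            annotation=Path(inp["annotation"]) if "annotation" in inp else None,
            annotation_format=inp.get("annotation_format"),
            manifest=Path(inp["manifest"]) if "manifest" in inp else None,
            center=bool(norm.get("center", True)),
            robust=bool(norm.get("robust", False)),
            promoter_cap=int(summ.get("promoter_cap", PROMOTER_CAP)),
            min_gene_length=int(summ.get("min_gene_length", MIN_GENE_LENGTH)),
            cluster_k=int(cluster["k"]) if "k" in cluster else None,
            cluster_experiments=list(cluster.get("experiments", [])),
            cluster_regions=list(cluster.get("regions", ["promoter", "orf"])),
            cluster_epochs=int(cluster.get("epochs", 100)),
            metagene_bin=int(mg.get("bin_width", 50)),
            metagene_span=int(mg.get("span", 300)),
            metagene_extent=int(mg.get("extent", 500)),
            metagene_stat=str(mg.get("stat", "mean")),
            trend_window=int(trend.get("window", 300)),
            trend_x=trend.get("x"),
            trend_y=trend.get("y"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        """Fail before any computation on structural config errors."""
        if (self.simulate is None) == (self.annotation is None):
            raise ValidationError(
                "config needs exactly one of a 'simulate' block or an "
                "'input' block with annotation + manifest"
            )
        if self.simulate is None:
            assert self.annotation is not None
            if not self.annotation.exists():
                raise ValidationError(f"annotation not found: {self.annotation}")
            if self.manifest is None or not self.manifest.exists():
                raise ValidationError(f"manifest not found: {self.manifest}")
        for name in ("promoter_cap", "min_gene_length", "metagene_bin",
                     "metagene_span", "metagene_extent", "trend_window",
                     "cluster_epochs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.cluster_k is not None and self.cluster_k < 1:
            raise ValidationError("cluster k must be >= 1")
        # constructing the config validates bin/span compatibility
        MetageneConfig(self.metagene_bin, self.metagene_span,
                       self.metagene_extent, self.metagene_stat)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every configured stage; returns the output directory.

    Writes: simulated inputs (when simulating), per-experiment Z-score
    bedGraphs, the per-gene summary TSV, cluster assignment/codebook TSVs,
    smoothed metagene TSVs per experiment, the trend-curve TSV and a
    ``run_manifest.json``.
    """
    config.validate()
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "FAILED"
    try:
        result = _run(config, outdir)
        if marker.exists():
            marker.unlink()
        return result
    except Exception as exc:
        marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _run(config: PipelineConfig, outdir: Path) -> Path:
    if config.simulate is not None:
        with _stage("simulate"):
            sim = dict(config.simulate)
            n_genes = int(sim.pop("n_genes", 300))
            sim.setdefault("seed", config.seed)
            if "efficiencies" in sim:
                sim["efficiencies"] = tuple(sim["efficiencies"])
            if "chromosome_lengths" in sim and sim["chromosome_lengths"]:
                sim["chromosome_lengths"] = tuple(
                    (str(c), int(l)) for c, l in sim["chromosome_lengths"]
                )
            fixture = make_fixture(
                seed=config.seed, n_genes=n_genes, config=SimulationConfig(**sim)
            )
            simdir = outdir / "simulated"
            write_fixture(fixture, simdir)
            annotation = fixture.genome.annotation
            manifest = load_manifest(simdir / "manifest.tsv")
            base_dir = simdir
    else:
        with _stage("ingest"):
            annotation = read_annotation(config.annotation, config.annotation_format)
            manifest = load_manifest(config.manifest)
            base_dir = Path(config.manifest).parent

    with _stage("normalize"):
        ztracks = process_manifest(
            manifest, base_dir, center=config.center, robust=config.robust
        )
        trackdir = outdir / "tracks"
        trackdir.mkdir(exist_ok=True)
        for exp, track in ztracks.items():
            write_track(track, trackdir / f"{exp}.zscore.bedGraph")

    with _stage("summarize"):
        summary = GeneSummaryTable.build(
            ztracks, annotation,
            min_length=config.min_gene_length,
            promoter_cap=config.promoter_cap,
        )
        summary.write(outdir / "summary.tsv")

    if config.cluster_k is not None:
        with _stage("cluster"):
            experiments = config.cluster_experiments or list(ztracks)
            fm = feature_matrix(summary, experiments, config.cluster_regions)
            model, nodes = som_fit(
                fm, config.cluster_k, epochs=config.cluster_epochs,
                seed=config.seed,
            )
            pd.DataFrame(
                {"gene_id": fm.gene_ids, "node": nodes}
            ).to_csv(outdir / "cluster_assignments.tsv", sep="\t", index=False)
            pd.DataFrame(
                model.codebook, columns=list(fm.feature_names)
            ).to_csv(outdir / "cluster_codebook.tsv", sep="\t",
                     index_label="node")

    with _stage("metagene"):
        mg_cfg = MetageneConfig(config.metagene_bin, config.metagene_span,
                                config.metagene_extent, config.metagene_stat)
        kept = filter_genes(annotation, config.min_gene_length)
        for exp, track in ztracks.items():
            profile = smooth_profile(
                aggregate_profile(track, kept.genes(), annotation, mg_cfg),
                mg_cfg,
            )
            profile.write(outdir / f"metagene_{exp}.tsv")

    if config.trend_x and config.trend_y:
        with _stage("trend"):
            xe, xr = config.trend_x.split(":")
            ye, yr = config.trend_y.split(":")
            curve = sliding_median_trend(
                summary.column(xe, xr).to_numpy(),
                summary.column(ye, yr).to_numpy(),
                window=config.trend_window,
                ids=list(summary.df.index),
            )
            curve.write(outdir / "trend.tsv")

    with _stage("manifest"):
        echo = dataclasses.asdict(config)
        echo = {k: (str(v) if isinstance(v, Path) else v) for k, v in echo.items()}
        (outdir / "run_manifest.json").write_text(
            json.dumps(
                {"config": echo, "seed": config.seed, "version": __version__},
                indent=2, sort_keys=True,
            )
            + "\n"
        )
    return outdir
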