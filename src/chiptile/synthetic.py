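"""Synthetic tiling-array ChIP experiments with planted ground truth.

The generator emulates the design of a whole-genome 60-mer tiling array on
a compact genome: probes every ~275 bp (+/-100 bp jitter), several
biological replicates per factor with differing immunoprecipitation
efficiencies, additive Gaussian noise and a few percent of missing probes.
Each gene carries one *occupancy archetype* — a phenomenological binding
shape (promoter-only plateau, uniform ORF binding, a 3'-skewed ramp, or
unbound) with exponential decay into the gene-proximal half of each
intergenic region.  The archetype table is the ground truth every
downstream stage is tested against.

Signals are defined at probe midpoints: with 60 bp probes on a ~275 bp
grid, averaging over the probe footprint would change values by far less
than the planted noise, so the midpoint evaluation keeps the truth model
exactly invertible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .summarize import define_promoters, promoter_length
from .tracks_io import (
    Gene,
    GeneAnnotation,
    ProbeTrack,
    ValidationError,
    write_annotation,
    write_track,
)

__all__ = [
    "OccupancyArchetype",
    "SimulationConfig",
    "GenomeModel",
    "ProbeLayout",
    "TruthTable",
    "generate_genome",
    "generate_probes",
    "simulate_experiment",
    "simulate_study",
    "DEFAULT_ARCHETYPE_WEIGHTS",
    "DEFAULT_FACTOR_ARCHETYPES",
    "Fixture",
    "make_fixture",
    "write_fixture",
]


class CapacityError(ValidationError):
    """A chromosome cannot hold the genes requested of it."""


# ---------------------------------------------------------------------------
# Configuration and truth types
# ---------------------------------------------------------------------------

_ORF_SHAPES = ("uniform", "ramp", "zero")


@dataclass(frozen=True)
class OccupancyArchetype:
    """One planted binding shape, in the units of the raw log2-ratio signal.

    promoter_level
        Plateau height over the operational promoter (min(250, half-IG)
        upstream of the 5' boundary), decaying exponentially beyond it.
    orf_shape / orf_amplitude
        ``uniform`` holds the amplitude across the gene body; ``ramp``
        rises linearly from 0 at the 5' end to the amplitude at the 3'
        end (the 3'-skewed pattern); ``zero`` leaves the body empty.
    ig_decay
        Exponential decay length (bp) of the signal bleeding into the
        gene-proximal half-intergenic regions.
    """

    archetype_id: str
    promoter_level: float
    orf_shape: str
    orf_amplitude: float = 0.0
    ig_decay: float = 200.0

    def __post_init__(self) -> None:
        if self.orf_shape not in _ORF_SHAPES:
            raise ValidationError(f"orf_shape must be one of {_ORF_SHAPES}")
        if not (math.isfinite(self.promoter_level) and math.isfinite(self.orf_amplitude)):
            raise ValidationError("archetype amplitudes must be finite")
        if not self.ig_decay > 0:
            raise ValidationError("ig_decay must be > 0")

    def mean_orf_level(self) -> float:
        if self.orf_shape == "uniform":
            return self.orf_amplitude
        if self.orf_shape == "ramp":
            return self.orf_amplitude / 2.0
        return 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Array design, replication and noise parameters of a simulated study.

    Defaults mirror the tiling-array design being emulated: probes every
    275 bp with +/-100 bp jitter, 60-mer probes, two biological replicates
    with a 1.6x efficiency spread, noise sd 0.3 (log2-ratio units) and 2%
    missing probes.  Gene lengths are log-normal, clipped to [300, 6000] bp
    so that both the 500 bp analysis filter and all three length bins
    (750–1500 / 1500–3000 / >3000) are exercised.
    """

    spacing_mean: int = 275
    spacing_jitter: int = 100
    probe_length: int = 60
    n_replicates: int = 2
    efficiencies: tuple[float, ...] = (1.0, 1.6)
    noise_sd: float = 0.3
    missing_fraction: float = 0.02
    seed: int = 0
    chromosome_lengths: tuple[tuple[str, int], ...] | None = None
    gene_length_log_mean: float = math.log(1400.0)
    gene_length_log_sd: float = 0.6
    gene_length_min: int = 300
    gene_length_max: int = 6000
    gap_min: int = 150
    gap_max: int = 900

    def __post_init__(self) -> None:
        if not (self.spacing_mean > self.spacing_jitter >= 0):
            raise ValidationError("need spacing_mean > spacing_jitter >= 0")
        if self.probe_length <= 0:
            raise ValidationError("probe_length must be positive")
        if self.n_replicates < 1:
            raise ValidationError("need at least one replicate")
        if len(self.efficiencies) != self.n_replicates:
            raise ValidationError("one efficiency per replicate required")
        if any(e <= 0 for e in self.efficiencies):
            raise ValidationError("efficiencies must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValidationError("missing_fraction must be in [0, 1)")
        if not (0 < self.gap_min <= self.gap_max):
            raise ValidationError("need 0 < gap_min <= gap_max")


@dataclass(frozen=True)
class GenomeModel:
    """A synthetic genome: annotation plus the planted archetype of each gene."""

    annotation: GeneAnnotation
    archetype_ids: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [g.gene_id for g in self.annotation
                   if g.gene_id not in self.archetype_ids]
        if missing:
            raise ValidationError(f"genes without archetype: {missing[:3]}...")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        assert self.annotation.chrom_lengths is not None
        return self.annotation.chrom_lengths


@dataclass(frozen=True)
class ProbeLayout:
    """Tiling-probe intervals per chromosome (no values attached)."""

    probes: Mapping[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (starts, ends)

    @property
    def n_probes(self) -> int:
        return sum(s.size for s, _ in self.probes.values())

    def midpoints(self, chrom: str) -> np.ndarray:
        starts, ends = self.probes[chrom]
        return (starts + ends) / 2.0


@dataclass(frozen=True)
class TruthTable:
    """Planted per-gene truth: archetype id, promoter level, mean ORF level."""

    df: pd.DataFrame  # index gene_id; archetype, true_promoter, true_orf_mean

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))


# ---------------------------------------------------------------------------
# Genome and probe generation
# ---------------------------------------------------------------------------

DEFAULT_ARCHETYPE_WEIGHTS: dict[str, float] = {
    "promoter_only": 0.30,
    "promoter_orf": 0.30,
    "unbound": 0.30,
    "orf_ramp": 0.10,
}


def _auto_chromosomes(config: SimulationConfig, n_genes: int) -> dict[str, int]:
    # generous sizing: mean footprint = E[gene length] + E[gap], doubled,
    # plus a flat margin so small gene counts never hit capacity by chance
    mean_len = math.exp(config.gene_length_log_mean + config.gene_length_log_sd**2 / 2)
    mean_len = min(mean_len, config.gene_length_max)
    footprint = mean_len + (config.gap_min + config.gap_max) / 2
    total = int(n_genes * footprint * 2.0) + 30_000
    return {"chrI": int(total * 0.6), "chrII": total - int(total * 0.6)}


def generate_genome(
    config: SimulationConfig,
    n_genes: int,
    seed: int,
    archetype_weights: Mapping[str, float] | None = None,
) -> GenomeModel:
    """Place ``n_genes`` non-overlapping stranded genes with planted archetypes.

    Genes are laid left-to-right with uniform intergenic gaps in
    [gap_min, gap_max] and log-normal lengths clipped to
    [gene_length_min, gene_length_max]; strands and archetypes are drawn
    at random.  Chromosomes come from ``config.chromosome_lengths`` or are
    auto-sized with headroom; explicit chromosomes that cannot hold their
    share of genes raise :class:`CapacityError` naming the chromosome.
    Deterministic given ``seed``.
    """
    if n_genes < 0:
        raise ValidationError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    weights = dict(archetype_weights or DEFAULT_ARCHETYPE_WEIGHTS)
    wsum = sum(weights.values())
    if wsum <= 0:
        raise ValidationError("archetype weights must have positive sum")
    arch_ids = sorted(weights)
    arch_p = np.array([weights[a] / wsum for a in arch_ids])

    if config.chromosome_lengths is not None:
        chroms = dict(config.chromosome_lengths)
    else:
        chroms = _auto_chromosomes(config, max(n_genes, 1))

    total_len = sum(chroms.values())
    quota = {c: int(round(n_genes * L / total_len)) for c, L in chroms.items()}
    # rounding may drop/add a gene; fix up on the largest chromosome
    largest = max(chroms, key=lambda c: chroms[c])
    quota[largest] += n_genes - sum(quota.values())

    genes: list[Gene] = []
    archetypes: dict[str, str] = {}
    idx = 0
    for chrom in sorted(chroms):
        clen = chroms[chrom]
        pos = int(rng.integers(config.gap_min, config.gap_max + 1))
        for _ in range(quota[chrom]):
            length = int(np.clip(
                round(rng.lognormal(config.gene_length_log_mean,
                                    config.gene_length_log_sd)),
                config.gene_length_min, config.gene_length_max,
            ))
            gap = int(rng.integers(config.gap_min, config.gap_max + 1))
            if pos + length + gap > clen:
                raise CapacityError(
                    f"chromosome {chrom} ({clen} bp) cannot hold its quota of "
                    f"{quota[chrom]} genes"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"g{idx:04d}"
            genes.append(Gene(gene_id, chrom, pos, pos + length, strand))
            archetypes[gene_id] = str(rng.choice(arch_ids, p=arch_p))
            pos += length + gap
            idx += 1
    annotation = GeneAnnotation(genes, chroms)
    return GenomeModel(annotation, archetypes)


def generate_probes(genome: GenomeModel, config: SimulationConfig) -> ProbeLayout:
    """Tile every chromosome with jittered probes.

    Successive probe starts differ by ``spacing_mean`` plus a uniform
    integer jitter in [-spacing_jitter, +spacing_jitter]; the first start
    is uniform in [0, jitter].  Probes extend ``probe_length`` bp and
    tiling stops at the chromosome end.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    j = config.spacing_jitter
    probes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in sorted(genome.chrom_lengths):
        clen = genome.chrom_lengths[chrom]
        starts: list[int] = []
        pos = int(rng.integers(0, j + 1)) if j > 0 else 0
        while pos + config.probe_length <= clen:
            starts.append(pos)
            pos += config.spacing_mean + (int(rng.integers(-j, j + 1)) if j > 0 else 0)
        arr = np.array(starts, dtype=np.int64)
        probes[chrom] = (arr, arr + config.probe_length)
    return ProbeLayout(probes)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _truth_on_chromosome(
    mids: np.ndarray,
    genes: Sequence[Gene],
    gaps: Mapping[str, tuple[float, float]],
    archetypes: Mapping[str, OccupancyArchetype],
    archetype_ids: Mapping[str, str],
) -> np.ndarray:
    """Noise-free occupancy evaluated at probe midpoints.

    Per gene: promoter plateau over min(250, half-IG) upstream of the 5'
    boundary, the ORF shape across the body, exponential decay of the
    boundary values into the remaining half-IG on both sides, 0 elsewhere.
    Half-IG ownership makes gene contributions disjoint, so summation is
    safe.
    """
    truth = np.zeros_like(mids, dtype=np.float64)
    for gene in genes:
        arch = archetypes[archetype_ids[gene.gene_id]]
        up_ig, down_ig = gaps[gene.gene_id]
        u_half = int(up_ig) // 2 if math.isfinite(up_ig) else 10**9
        d_half = int(down_ig) // 2 if math.isfinite(down_ig) else 10**9
        plen = promoter_length(up_ig)
        s, e, L = gene.start, gene.end, gene.length
        if gene.strand == "+":
            dist5 = mids - s          # >=0 inside gene, <0 upstream
            dist3 = mids - e          # >=0 downstream
        else:
            dist5 = e - mids
            dist3 = s - mids
        in_gene = (dist5 >= 0) & (dist5 < L)
        in_prom = (dist5 < 0) & (dist5 >= -plen)
        in_updec = (dist5 < -plen) & (dist5 >= -u_half)
        in_down = (dist3 >= 0) & (dist3 < d_half)

        if arch.orf_shape == "uniform":
            body = np.full(mids.shape, arch.orf_amplitude)
            end3 = arch.orf_amplitude
        elif arch.orf_shape == "ramp":
            body = arch.orf_amplitude * dist5 / L
            end3 = arch.orf_amplitude
        else:
            body = np.zeros(mids.shape)
            end3 = 0.0
        truth[in_gene] += body[in_gene]
        truth[in_prom] += arch.promoter_level
        truth[in_updec] += arch.promoter_level * np.exp(
            -(-dist5[in_updec] - plen) / arch.ig_decay
        )
        truth[in_down] += end3 * np.exp(-dist3[in_down] / arch.ig_decay)
    return truth


def true_signal(
    genome: GenomeModel,
    probes: ProbeLayout,
    archetypes: Mapping[str, OccupancyArchetype],
) -> dict[str, np.ndarray]:
    """Noise-free signal per chromosome for one factor's archetype table."""
    gaps = genome.annotation.intergenic_gaps()
    out: dict[str, np.ndarray] = {}
    for chrom, (starts, ends) in probes.probes.items():
        if chrom not in genome.chrom_lengths:
            raise ValidationError(f"probes on unknown chromosome {chrom}")
        mids = (starts + ends) / 2.0
        out[chrom] = _truth_on_chromosome(
            mids, genome.annotation.genes(chrom), gaps, archetypes,
            genome.archetype_ids,
        )
    return out


def simulate_experiment(
    genome: GenomeModel,
    probes: ProbeLayout,
    config: SimulationConfig,
    archetypes: Mapping[str, OccupancyArchetype],
    experiment_id: str = "experiment",
    seed: int | None = None,
) -> tuple[list[ProbeTrack], TruthTable]:
    """Simulate one factor's replicate tracks and its truth table.

    Replicate ``r`` observes ``efficiency_r * truth(midpoint) + N(0, sd)``
    with a ``missing_fraction`` of probes set to NaN.  Deterministic given
    the seed (``config.seed`` when none is passed).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = true_signal(genome, probes, archetypes)
    tracks: list[ProbeTrack] = []
    for r in range(config.n_replicates):
        eff = config.efficiencies[r]
        data = {}
        for chrom, (starts, ends) in sorted(probes.probes.items()):
            vals = eff * truth[chrom]
            if config.noise_sd > 0:
                vals = vals + rng.normal(0.0, config.noise_sd, size=vals.shape)
            else:
                vals = vals.copy()
            if config.missing_fraction > 0:
                vals[rng.random(vals.shape) < config.missing_fraction] = np.nan
            data[chrom] = (starts, ends, vals)
        tracks.append(ProbeTrack(f"{experiment_id}_rep{r + 1}", data))

    rows = []
    gaps = genome.annotation.intergenic_gaps()
    for gene in genome.annotation:
        arch = archetypes[genome.archetype_ids[gene.gene_id]]
        plen = promoter_length(gaps[gene.gene_id][0])
        rows.append((
            gene.gene_id,
            arch.archetype_id,
            arch.promoter_level if plen > 0 else 0.0,
            arch.mean_orf_level(),
        ))
    tdf = pd.DataFrame(
        rows, columns=["gene_id", "archetype", "true_promoter", "true_orf_mean"]
    ).set_index("gene_id")
    return tracks, TruthTable(tdf)


def simulate_study(
    genome: GenomeModel,
    probes: ProbeLayout,
    config: SimulationConfig,
    factors: Mapping[str, Mapping[str, OccupancyArchetype]],
    seed: int | None = None,
) -> dict[str, tuple[list[ProbeTrack], TruthTable]]:
    """Simulate several factors over the same genome and probe layout."""
    base = config.seed if seed is None else seed
    out = {}
    for i, (name, archetypes) in enumerate(factors.items()):
        out[name] = simulate_experiment(
            genome, probes, config, archetypes, experiment_id=name,
            seed=(base + 10_007 * (i + 1)) % (2**31),
        )
    return out


# ---------------------------------------------------------------------------
# Default study: three factors over four archetypes
# ---------------------------------------------------------------------------

def _arch(aid, prom, shape, amp=0.0, decay=150.0):
    return OccupancyArchetype(aid, prom, shape, amp, decay)


#: Factor-specific archetype tables for the packaged study.  The factors
#: play the roles of a promoter+ORF deacetylase complex ("rpd3"), its
#: ORF-restricted form ("rco1", the small-complex subunit), and elongating
#: polymerase ("rnapii"); "orf_ramp" genes carry the 3'-skewed pattern.
DEFAULT_FACTOR_ARCHETYPES: dict[str, dict[str, OccupancyArchetype]] = {
    "rpd3": {
        "promoter_only": _arch("promoter_only", 2.0, "zero"),
        "promoter_orf": _arch("promoter_orf", 2.0, "uniform", 1.5),
        "unbound": _arch("unbound", 0.0, "zero"),
        "orf_ramp": _arch("orf_ramp", 0.5, "uniform", 1.2),
    },
    "rco1": {
        "promoter_only": _arch("promoter_only", 0.0, "zero"),
        "promoter_orf": _arch("promoter_orf", 0.3, "uniform", 1.5),
        "unbound": _arch("unbound", 0.0, "zero"),
        "orf_ramp": _arch("orf_ramp", 0.0, "ramp", 1.5),
    },
    "rnapii": {
        "promoter_only": _arch("promoter_only", 0.2, "zero"),
        "promoter_orf": _arch("promoter_orf", 0.5, "uniform", 1.5),
        "unbound": _arch("unbound", 0.0, "zero"),
        "orf_ramp": _arch("orf_ramp", 0.5, "uniform", 1.5),
    },
}


@dataclass
class Fixture:
    """A complete small simulated study used throughout the test suite."""

    genome: GenomeModel
    probes: ProbeLayout
    config: SimulationConfig
    factors: dict[str, tuple[list[ProbeTrack], TruthTable]]


def make_fixture(
    seed: int = 0,
    n_genes: int = 300,
    config: SimulationConfig | None = None,
    factors: Mapping[str, Mapping[str, OccupancyArchetype]] | None = None,
) -> Fixture:
    """Two chromosomes, ~300 genes, three factors x two replicates."""
    cfg = config if config is not None else SimulationConfig(seed=seed)
    cfg = replace(cfg, seed=seed)
    genome = generate_genome(cfg, n_genes, seed=seed)
    probes = generate_probes(genome, cfg)
    study = simulate_study(
        genome, probes, cfg, factors or DEFAULT_FACTOR_ARCHETYPES, seed=seed
    )
    return Fixture(genome, probes, cfg, study)


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Write annotation (GFF3 + BED), replicate bedGraphs, truth TSVs and a
    replicate manifest TSV into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_annotation(fixture.genome.annotation, outdir / "annotation.gff3")
    write_annotation(fixture.genome.annotation, outdir / "annotation.bed")
    manifest_rows = []
    for factor, (tracks, truth) in fixture.factors.items():
        truth.write(outdir / f"{factor}.truth.tsv")
        for track in tracks:
            fname = f"{track.experiment_id}.bedGraph"
            write_track(track, outdir / fname)
            manifest_rows.append((factor, "IP-vs-input", fname))
    pd.DataFrame(
        manifest_rows, columns=["experiment", "role", "path"]
    ).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
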