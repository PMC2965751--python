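"""Per-gene promoter/ORF occupancy summaries from probe-level Z-tracks.

The promoter of a gene is the upstream region of length
``min(250 bp, floor(IG/2))`` abutting its 5' boundary, where IG is the
intergenic gap to the nearest neighboring gene (strand-aware; first/last
genes measure to the chromosome edge).  Compact genomes make this half-IG
cap essential: it guarantees two promoters never claim the same probe.

Summaries are the median Z-score of the probes whose *midpoint* falls in a
region, computed without interpolation — a probe either contributes fully
or not at all.  Genes shorter than 500 bp are excluded from analysis, and
genes are binned by length (750–1500, 1500–3000, >3000 bp) for the
length-stratified profile comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks_io import (
    Gene,
    GeneAnnotation,
    ProbeTrack,
    ValidationError,
    read_summary,
    write_summary,
)

__all__ = [
    "PROMOTER_CAP",
    "MIN_GENE_LENGTH",
    "LENGTH_BIN_LABELS",
    "PromoterRegion",
    "define_promoters",
    "promoter_length",
    "median_summary",
    "filter_genes",
    "assign_length_bins",
    "GeneSummaryTable",
]

#: Upper bound on promoter length in bp.
PROMOTER_CAP = 250
#: Genes shorter than this are excluded from all analyses.
MIN_GENE_LENGTH = 500
#: Length-bin labels, shortest first.
LENGTH_BIN_LABELS = ("750-1500", "1500-3000", ">3000", "unbinned")


def promoter_length(upstream_ig: float, cap: int = PROMOTER_CAP) -> int:
    """min(cap, floor(IG/2)); an infinite (unknown) gap yields the cap."""
    if math.isinf(upstream_ig):
        return cap
    return min(cap, int(upstream_ig) // 2)


@dataclass(frozen=True)
class PromoterRegion:
    """The operational promoter of one gene, 0-based half-open.

    ``zero_length`` flags genes whose upstream gap is 0 or 1 bp; such
    promoters contain no probes and summarize to missing.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    zero_length: bool = field(default=False, compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start


def define_promoters(
    annotation: GeneAnnotation, cap: int = PROMOTER_CAP
) -> dict[str, PromoterRegion]:
    """Promoter region for every gene: min(cap, half upstream IG), 5' side.

    Strand-aware: the promoter of a '+' gene ends at its start coordinate;
    the promoter of a '-' gene begins at its end coordinate.  The half-IG
    cap (floor division) makes promoters of neighboring genes disjoint by
    construction; this is asserted, not repaired.
    """
    gaps = annotation.intergenic_gaps()
    promoters: dict[str, PromoterRegion] = {}
    for gene in annotation:
        up_ig, _ = gaps[gene.gene_id]
        plen = promoter_length(up_ig, cap)
        if gene.strand == "+":
            region = PromoterRegion(
                gene.gene_id, gene.chrom, gene.start - plen, gene.start,
                gene.strand, zero_length=plen == 0,
            )
        else:
            region = PromoterRegion(
                gene.gene_id, gene.chrom, gene.end, gene.end + plen,
                gene.strand, zero_length=plen == 0,
            )
        promoters[gene.gene_id] = region
    # Disjointness holds by the half-IG construction; verify defensively.
    by_chrom: dict[str, list[PromoterRegion]] = {}
    for p in promoters.values():
        if p.length > 0:
            by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, regs in by_chrom.items():
        regs.sort(key=lambda p: p.start)
        for a, b in zip(regs, regs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"promoters of {a.gene_id} and {b.gene_id} overlap on {chrom}"
                )
    return promoters


def filter_genes(
    annotation: GeneAnnotation, min_length: int = MIN_GENE_LENGTH
) -> GeneAnnotation:
    """Keep genes with length >= ``min_length`` (inclusive), order preserved."""
    return GeneAnnotation(
        (g for g in annotation if g.length >= min_length),
        annotation.chrom_lengths,
    )


def assign_length_bins(annotation: GeneAnnotation) -> dict[str, str]:
    """Gene length bins: [750,1500) / [1500,3000] / (3000,inf); else unbinned.

    3000 bp belongs to the middle bin (the top bin is strictly >3000) and
    1500 bp to the middle bin (half-open lower bins).
    """
    bins: dict[str, str] = {}
    for g in annotation:
        if g.length < 750:
            bins[g.gene_id] = "unbinned"
        elif g.length < 1500:
            bins[g.gene_id] = "750-1500"
        elif g.length <= 3000:
            bins[g.gene_id] = "1500-3000"
        else:
            bins[g.gene_id] = ">3000"
    return bins


def _region_median(
    mids: np.ndarray, values: np.ndarray, start: int, end: int
) -> tuple[float, int]:
    """Median of non-missing values whose probe midpoint lies in [start, end)."""
    lo = int(np.searchsorted(mids, start, side="left"))
    hi = int(np.searchsorted(mids, end, side="left"))
    vals = values[lo:hi]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return math.nan, 0
    return float(np.median(vals)), int(vals.size)


def median_summary(
    track: ProbeTrack,
    annotation: GeneAnnotation,
    promoters: Mapping[str, PromoterRegion] | None = None,
) -> pd.DataFrame:
    """Per-gene promoter/ORF median of one experiment's Z-track.

    Returns a DataFrame indexed by gene id with columns ``promoter``,
    ``orf``, ``promoter_n``, ``orf_n``.  A probe contributes to a region
    iff its midpoint lies inside it; a region with no (non-missing) probe
    summarizes to NaN with count 0.
    """
    if promoters is None:
        promoters = define_promoters(annotation)
    rows = []
    mid_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in track.chromosomes:
        mid_cache[chrom] = (track.midpoints(chrom), track.arrays(chrom)[2])
    empty = (np.empty(0), np.empty(0))
    for gene in annotation:
        mids, values = mid_cache.get(gene.chrom, empty)
        prom = promoters[gene.gene_id]
        pmed, pn = _region_median(mids, values, prom.start, prom.end)
        omed, on = _region_median(mids, values, gene.start, gene.end)
        rows.append((gene.gene_id, pmed, omed, pn, on))
    df = pd.DataFrame(
        rows, columns=["gene_id", "promoter", "orf", "promoter_n", "orf_n"]
    ).set_index("gene_id")
    return df


@dataclass
class GeneSummaryTable:
    """Per-gene promoter/ORF medians across experiments, plus length metadata.

    ``df`` is indexed by gene id with columns ``length``, ``length_bin``
    and, per experiment E, ``E_promoter``, ``E_orf``, ``E_promoter_n``,
    ``E_orf_n``.  Genes below the length threshold are absent.
    """

    df: pd.DataFrame
    experiments: tuple[str, ...]

    @classmethod
    def build(
        cls,
        tracks: Mapping[str, ProbeTrack],
        annotation: GeneAnnotation,
        min_length: int = MIN_GENE_LENGTH,
        promoter_cap: int = PROMOTER_CAP,
    ) -> "GeneSummaryTable":
        """Summarize every experiment over the length-filtered genes.

        Promoters and intergenic gaps are defined on the *full* annotation
        (short genes still bound their neighbors' gaps); the length filter
        only selects which genes are reported.
        """
        promoters = define_promoters(annotation, promoter_cap)
        kept = filter_genes(annotation, min_length)
        bins = assign_length_bins(kept)
        base = pd.DataFrame(
            {
                "length": [g.length for g in kept],
                "length_bin": [bins[g.gene_id] for g in kept],
            },
            index=pd.Index([g.gene_id for g in kept], name="gene_id"),
        )
        parts = [base]
        experiments = tuple(tracks)
        for exp in experiments:
            sub = median_summary(tracks[exp], kept, promoters)
            sub.columns = [f"{exp}_{c}" for c in sub.columns]
            parts.append(sub)
        return cls(pd.concat(parts, axis=1), experiments)

    def column(self, experiment: str, region: str) -> pd.Series:
        """One (experiment, region) median column; region is promoter|orf."""
        if region not in ("promoter", "orf"):
            raise ValidationError(f"region must be promoter or orf, got {region!r}")
        return self.df[f"{experiment}_{region}"]

    def write(self, path) -> None:
        write_summary(self, path)

    @classmethod
    def read(cls, path) -> "GeneSummaryTable":
        df = read_summary(path)
        experiments = tuple(
            dict.fromkeys(
                c.removesuffix("_promoter")
                for c in df.columns
                if c.endswith("_promoter")
            )
        )
        return cls(df, experiments)

    def __len__(self) -> int:
        return len(self.df)
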