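"""Dual-anchored metagene occupancy profiles.

Signal is mapped onto the 5' and 3' boundaries of each gene in 50 bp
windows covering each half-gene plus the adjacent half-intergenic region,
then averaged across a gene set and smoothed with a 300 bp sliding window.
Anchoring both ends separately (rather than rescaling genes to a common
length) preserves absolute distances from the boundaries, which is what a
positioned promoter peak or a 3'-skewed ORF ramp looks like in bp.

Offsets are strand-aware and always run 5'->3': on the 5' arm, negative
offsets lie in the upstream half-IG and positive offsets inside the 5'
half of the gene; on the 3' arm, negative offsets lie inside the 3' half
and positive offsets in the downstream half-IG.  Each gene contributes
only where it has probes, so per-bin contributing-gene counts accompany
every value; bins with no contributor are missing, never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks_io import Gene, GeneAnnotation, ProbeTrack, ValidationError

__all__ = [
    "MetageneConfig",
    "MetageneProfile",
    "anchored_offset",
    "aggregate_profile",
    "smooth_profile",
]

ARMS = ("5p", "3p")


@dataclass(frozen=True)
class MetageneConfig:
    """Binning/smoothing parameters of a metagene profile.

    bin_width
        Window size in bp for mapping probes onto the anchors (50 bp).
    span
        Sliding smoothing window in bp (300 bp = 6 bins at defaults);
        must be a positive multiple of ``bin_width``.
    extent
        How far the arms reach into the half-IGs, in bp; each gene is
        additionally truncated at floor(IG/2) so neighboring genes never
        double-claim an intergenic probe.
    stat
        Across-genes aggregation statistic, ``mean`` (default) or
        ``median``.
    """

    bin_width: int = 50
    span: int = 300
    extent: int = 500
    stat: str = "mean"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be positive")
        if self.span <= 0 or self.span % self.bin_width != 0:
            raise ValidationError("span must be a positive multiple of bin_width")
        if self.extent < 0:
            raise ValidationError("extent must be >= 0")
        if self.stat not in ("mean", "median"):
            raise ValidationError("stat must be 'mean' or 'median'")


@dataclass
class MetageneProfile:
    """Aggregate profile over a gene set, one row per (arm, offset) bin.

    ``df`` columns: ``arm`` ("5p"/"3p"), ``offset`` (bin left edge in bp
    relative to the arm's anchor), ``value`` (aggregate, NaN where no gene
    contributes) and ``n`` (contributing genes).  Bin rows are contiguous
    within each arm.
    """

    df: pd.DataFrame
    bin_width: int
    n_genes: int

    def arm(self, which: str) -> pd.DataFrame:
        if which not in ARMS:
            raise ValidationError(f"arm must be one of {ARMS}")
        return self.df[self.df["arm"] == which].reset_index(drop=True)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def anchored_offset(
    gene: Gene,
    midpoint: float,
    upstream_half: float,
    downstream_half: float,
    extent: int,
) -> tuple[str, float] | None:
    """Map one probe midpoint onto a gene's anchored coordinate system.

    Returns ``(arm, offset)`` or None when the position falls outside the
    gene and its truncated half-IGs.  Positions strictly before half the
    gene length belong to the 5' arm; the rest of the gene to the 3' arm
    (deterministic tie-break for odd lengths).
    """
    L = gene.length
    if gene.strand == "+":
        d5 = midpoint - gene.start
        d3 = midpoint - gene.end
    else:
        d5 = gene.end - midpoint
        d3 = gene.start - midpoint
    up_reach = min(extent, upstream_half)
    down_reach = min(extent, downstream_half)
    if -up_reach <= d5 < 0:
        return ("5p", d5)
    if 0 <= d5 < L / 2:
        return ("5p", d5)
    if 0 <= d5 < L:  # 3' half of the gene: offset negative from the 3' anchor
        return ("3p", d3)
    if 0 <= d3 < down_reach:
        return ("3p", d3)
    return None


def _per_gene_bins(
    gene: Gene,
    mids: np.ndarray,
    values: np.ndarray,
    gaps: tuple[float, float],
    config: MetageneConfig,
) -> dict[tuple[str, int], float]:
    """Mean probe value per (arm, bin) for one gene; NaN probes dropped."""
    up_ig, down_ig = gaps
    u_half = math.floor(up_ig / 2) if math.isfinite(up_ig) else config.extent
    d_half = math.floor(down_ig / 2) if math.isfinite(down_ig) else config.extent
    lo = gene.start - config.extent - 1
    hi = gene.end + config.extent + 1
    i0 = int(np.searchsorted(mids, lo))
    i1 = int(np.searchsorted(mids, hi))
    acc: dict[tuple[str, int], list[float]] = {}
    for m, v in zip(mids[i0:i1], values[i0:i1]):
        if math.isnan(v):
            continue
        hit = anchored_offset(gene, float(m), u_half, d_half, config.extent)
        if hit is None:
            continue
        arm, off = hit
        b = math.floor(off / config.bin_width)
        acc.setdefault((arm, b), []).append(float(v))
    return {key: float(np.mean(vals)) for key, vals in acc.items()}


def aggregate_profile(
    track: ProbeTrack,
    genes: Iterable[Gene] | Iterable[str],
    annotation: GeneAnnotation,
    config: MetageneConfig = MetageneConfig(),
) -> MetageneProfile:
    """Average a Z-track over a gene set in anchored 50 bp bins.

    Two-stage aggregation: probe values are averaged per gene per bin
    first, then the across-genes statistic (mean or median) is taken per
    bin, so long genes with many probes do not dominate.  Each bin records
    how many genes contributed; empty gene sets are an error.
    """
    gene_list: list[Gene] = [
        annotation.get(g) if isinstance(g, str) else g for g in genes
    ]
    if not gene_list:
        raise ValidationError("aggregate_profile: empty gene set")
    gaps = annotation.intergenic_gaps()
    per_bin: dict[tuple[str, int], list[float]] = {}
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in track.chromosomes:
        cache[chrom] = (track.midpoints(chrom), track.arrays(chrom)[2])
    for gene in gene_list:
        if gene.chrom not in cache:
            continue
        mids, values = cache[gene.chrom]
        for key, val in _per_gene_bins(
            gene, mids, values, gaps[gene.gene_id], config
        ).items():
            per_bin.setdefault(key, []).append(val)

    rows = []
    for arm in ARMS:
        arm_bins = [b for (a, b) in per_bin if a == arm]
        if not arm_bins:
            continue
        for b in range(min(arm_bins), max(arm_bins) + 1):
            contrib = per_bin.get((arm, b), [])
            if contrib:
                value = float(np.mean(contrib)) if config.stat == "mean" \
                    else float(np.median(contrib))
            else:
                value = math.nan
            rows.append((arm, b * config.bin_width, value, len(contrib)))
    df = pd.DataFrame(rows, columns=["arm", "offset", "value", "n"])
    return MetageneProfile(df, config.bin_width, len(gene_list))


def smooth_profile(
    profile: MetageneProfile, config: MetageneConfig = MetageneConfig()
) -> MetageneProfile:
    """Centered moving average over ``span / bin_width`` consecutive bins.

    Missing bins are ignored inside the window and the window shrinks at
    the arm edges, so the smoothed extrema never leave the range of the
    raw profile.  Contributing counts propagate as the minimum count over
    the window's non-missing bins.  ``span == bin_width`` is the identity.
    """
    w = config.span // config.bin_width
    if w * config.bin_width != config.span:
        raise ValidationError("span must be a multiple of bin_width")
    half_lo = w // 2              # bins before the center
    half_hi = w - half_lo - 1     # bins after the center
    parts = []
    for arm in ARMS:
        sub = profile.df[profile.df["arm"] == arm].reset_index(drop=True)
        if sub.empty:
            continue
        vals = sub["value"].to_numpy()
        ns = sub["n"].to_numpy()
        sm = np.full(vals.shape, math.nan)
        sn = np.zeros(ns.shape, dtype=np.int64)
        for i in range(vals.size):
            lo = max(0, i - half_lo)
            hi = min(vals.size, i + half_hi + 1)
            window = vals[lo:hi]
            mask = ~np.isnan(window)
            if mask.any():
                sm[i] = float(np.mean(window[mask]))
                sn[i] = int(ns[lo:hi][mask].min())
        out = sub.copy()
        out["value"] = sm
        out["n"] = sn
        parts.append(out)
    df = pd.concat(parts, ignore_index=True) if parts else profile.df.copy()
    return MetageneProfile(df, profile.bin_width, profile.n_genes)
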