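"""Replicate combination, Z-score standardization and difference tracks.

Biological replicates of one experiment are combined as a per-probe
weighted average; by default each replicate is weighted by the inverse of
the variance of its non-missing values, so noisier arrays count less.
Each replicate is first median-centered (standard two-color practice: it
removes the array-level offset the weighting cannot).

The combined log2-ratio track is then converted to a Z-score track,
``z_i = (x_i - mean) / sd`` over all non-missing probes of the experiment
(population sd).  Standardization makes experiments comparable despite
large differences in immunoprecipitation efficiency between factors: any
positive rescaling of a track yields the identical Z-track.

Difference tracks (per-probe a - b) serve two roles: normalizing an
acetylation signal to nucleosome density (acetyl minus histone), and
mutant-minus-wild-type occupancy change maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks_io import (
    GridMismatchError,
    ProbeTrack,
    ValidationError,
    ZScoreTrack,
    read_track,
)

__all__ = [
    "ReplicateSet",
    "align_to_union",
    "median_center",
    "combine_replicates",
    "zscore",
    "subtract_tracks",
    "load_manifest",
    "process_manifest",
]


def align_to_union(tracks: Sequence[ProbeTrack]) -> list[ProbeTrack]:
    """Re-grid tracks onto the union of their probe intervals.

    bedGraph output omits missing probes, so replicates read back from
    disk may cover slightly different probe subsets.  Probes absent from a
    track become NaN on the union grid.  Intervals that overlap without
    being identical across tracks are a real grid conflict and raise
    :class:`GridMismatchError`.
    """
    chroms = sorted({c for t in tracks for c in t.chromosomes})
    union: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in chroms:
        pairs = set()
        for t in tracks:
            if chrom in t.chromosomes:
                s, e, _ = t.arrays(chrom)
                pairs.update(zip(s.tolist(), e.tolist()))
        ordered = sorted(pairs)
        starts = np.array([p[0] for p in ordered], dtype=np.int64)
        ends = np.array([p[1] for p in ordered], dtype=np.int64)
        if starts.size and np.any(starts[1:] < ends[:-1]):
            raise GridMismatchError(
                f"{chrom}: probe intervals of the replicates overlap "
                "without being identical"
            )
        union[chrom] = (starts, ends)

    aligned: list[ProbeTrack] = []
    for t in tracks:
        data = {}
        for chrom, (starts, ends) in union.items():
            vals = np.full(starts.shape, np.nan)
            if chrom in t.chromosomes:
                s, e, v = t.arrays(chrom)
                idx = np.searchsorted(starts, s)
                vals[idx] = v
            data[chrom] = (starts, ends, vals)
        aligned.append(ProbeTrack(t.experiment_id, data))
    return aligned


@dataclass
class ReplicateSet:
    """Replicate tracks of one experiment on a shared probe grid."""

    experiment_id: str
    tracks: list[ProbeTrack]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValidationError("a ReplicateSet needs at least one track")
        ref = self.tracks[0]
        for t in self.tracks[1:]:
            if not ref.same_grid(t):
                raise GridMismatchError(
                    f"{self.experiment_id}: replicate probe grids differ "
                    "(align_to_union can reconcile missing-probe gaps)"
                )
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=np.float64)
            if self.weights.shape != (len(self.tracks),):
                raise ValidationError("one weight per replicate required")
            if np.any(self.weights < 0) or self.weights.sum() <= 0:
                raise ValidationError("weights must be >=0 with positive sum")

    @classmethod
    def from_tracks(
        cls,
        experiment_id: str,
        tracks: Sequence[ProbeTrack],
        weights: Sequence[float] | None = None,
        align: bool = False,
    ) -> "ReplicateSet":
        tl = align_to_union(tracks) if align else list(tracks)
        w = None if weights is None else np.asarray(weights, dtype=np.float64)
        return cls(experiment_id, tl, w)


def median_center(track: ProbeTrack) -> ProbeTrack:
    """Subtract the track-wide median of the non-missing values."""
    vals = track.all_values()
    finite = vals[~np.isnan(vals)]
    if finite.size == 0:
        return track
    med = float(np.median(finite))
    return track.with_values(
        {chrom: v - med for chrom, (_, _, v) in track.items()}
    )


def _inverse_variance_weights(tracks: Sequence[ProbeTrack]) -> np.ndarray:
    """1/variance of each replicate's non-missing values; uniform when any
    replicate is (near-)constant."""
    variances = []
    for t in tracks:
        vals = t.all_values()
        finite = vals[~np.isnan(vals)]
        variances.append(float(np.var(finite)) if finite.size else 0.0)
    if any(v == 0.0 for v in variances):
        return np.ones(len(tracks))
    return 1.0 / np.asarray(variances)


def combine_replicates(reps: ReplicateSet, center: bool = True) -> ProbeTrack:
    """Weighted per-probe average of the replicates.

    At each probe the weights are renormalized over the replicates with a
    non-missing value there, so a probe is missing in the output only when
    it is missing in every replicate.  Default weights are inverse
    variances (uniform fallback if any replicate has zero variance);
    ``center=True`` median-centers each replicate first.
    """
    tracks = [median_center(t) for t in reps.tracks] if center else reps.tracks
    weights = reps.weights if reps.weights is not None \
        else _inverse_variance_weights(tracks)
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in tracks[0].chromosomes:
        starts, ends, _ = tracks[0].arrays(chrom)
        stack = np.vstack([t.arrays(chrom)[2] for t in tracks])  # R x n
        present = ~np.isnan(stack)
        w = weights[:, None] * present
        wsum = w.sum(axis=0)
        num = np.nansum(np.where(present, stack, 0.0) * w, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            combined = np.where(wsum > 0, num / np.where(wsum > 0, wsum, 1.0), np.nan)
        out[chrom] = (starts, ends, combined)
    return ProbeTrack(reps.experiment_id, out)


def zscore(track: ProbeTrack, robust: bool = False) -> ProbeTrack:
    """Standardize a track: ``(x - location) / scale`` over non-missing probes.

    Default location/scale are the mean and population standard deviation,
    yielding a :class:`ZScoreTrack` (mean 0, sd 1).  ``robust=True`` uses
    median and 1.4826*MAD instead and returns a plain :class:`ProbeTrack`:
    a median/MAD-standardized track has median 0, not mean 0, so the
    Z-track invariant does not apply to it.  A constant or (near-)empty
    track has no scale and raises :class:`ValidationError`.  Missing
    probes stay missing; ranks of the non-missing values are preserved
    exactly.
    """
    vals = track.all_values()
    finite = vals[~np.isnan(vals)]
    if finite.size < 2 or np.all(finite == finite[0]):
        raise ValidationError(
            f"{track.experiment_id}: cannot Z-score a constant or empty track"
        )
    if robust:
        loc = float(np.median(finite))
        scale = 1.4826 * float(np.median(np.abs(finite - loc)))
        if scale == 0.0:
            raise ValidationError(
                f"{track.experiment_id}: zero MAD, robust Z-score undefined"
            )
    else:
        loc = float(np.mean(finite))
        scale = float(np.std(finite))  # population sd
    data = {
        chrom: (s, e, (v - loc) / scale) for chrom, (s, e, v) in track.items()
    }
    cls = ProbeTrack if robust else ZScoreTrack
    return cls(track.experiment_id, data)


def subtract_tracks(a: ProbeTrack, b: ProbeTrack) -> ProbeTrack:
    """Per-probe ``a - b`` on an identical grid; missing if either is missing."""
    if not a.same_grid(b):
        raise GridMismatchError(
            f"cannot subtract {b.experiment_id} from {a.experiment_id}: "
            "probe grids differ"
        )
    data = {}
    for chrom, (s, e, va) in a.items():
        vb = b.arrays(chrom)[2]
        data[chrom] = (s, e, va - vb)
    return ProbeTrack(f"{a.experiment_id}-{b.experiment_id}", data)


# ---------------------------------------------------------------------------
# Manifest-driven batch processing
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read the experiment manifest TSV: experiment, role, path (one row
    per replicate file)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"experiment", "role", "path"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"manifest must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return df


def process_manifest(
    manifest: pd.DataFrame,
    base_dir: str | Path,
    center: bool = True,
    robust: bool = False,
) -> dict[str, ZScoreTrack]:
    """Combine each experiment's replicates and Z-score the result.

    Order of operations: per-array median centering, weighted replicate
    combination, then standardization of the combined track.
    """
    base = Path(base_dir)
    out: dict[str, ZScoreTrack] = {}
    for exp, group in manifest.groupby("experiment", sort=True):
        tracks = [
            read_track(base / p, experiment_id=f"{exp}_rep{i + 1}")
            for i, p in enumerate(group["path"])
        ]
        reps = ReplicateSet.from_tracks(exp, tracks, align=True)
        combined = combine_replicates(reps, center=center)
        out[str(exp)] = zscore(combined, robust=robust)
    return out
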