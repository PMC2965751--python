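"""Interval/signal data model and I/O for the text formats the pipeline touches.

Every coordinate held in memory is 0-based, half-open ``[start, end)``.
Conversions to and from 1-based inclusive GFF3 happen only at the file
boundary, so no off-by-one logic exists anywhere downstream.  Missing probe
values are IEEE NaN — never zero — and missing probes are *omitted* from
bedGraph output rather than written as sentinels.

The two central containers are :class:`GeneAnnotation` (ordered, stranded,
non-overlapping gene intervals per chromosome, the role a curated genome
annotation plays) and :class:`ProbeTrack` (sorted, non-overlapping probe
intervals carrying one real value each, the role a normalized tiling-array
experiment plays).  :class:`ZScoreTrack` is a :class:`ProbeTrack` whose
non-missing values are standardized to mean 0 and standard deviation 1.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "GridMismatchError",
    "Gene",
    "GeneAnnotation",
    "ProbeTrack",
    "ZScoreTrack",
    "read_annotation",
    "write_annotation",
    "read_track",
    "write_track",
    "write_summary",
    "read_summary",
]


class ValidationError(ValueError):
    """An input violates a structural invariant of the data model."""


class FormatError(ValidationError):
    """A file could not be parsed; carries the offending line number."""


class GridMismatchError(ValidationError):
    """Two tracks that must share a probe grid do not."""


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """One protein-coding gene interval, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Coordinate of the 5' boundary (start for '+', end for '-')."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Coordinate of the 3' boundary."""
        return self.end if self.strand == "+" else self.start


class GeneAnnotation:
    """Ordered, stranded, pairwise non-overlapping genes per chromosome.

    Overlapping genes are rejected outright: the half-intergenic promoter
    rule is undefined for overlaps, so ambiguity is surfaced at load time
    rather than silently resolved.

    Parameters
    ----------
    genes
        Gene records in any order; they are sorted by (chrom, start).
    chrom_lengths
        Optional chromosome sizes in bp.  When present, genes are checked
        against the bounds and first/last intergenic gaps are measured to
        the chromosome edges; when absent the outer gaps are unbounded.
    """

    def __init__(
        self,
        genes: Iterable[Gene],
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> None:
        by_chrom: dict[str, list[Gene]] = {}
        by_id: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in by_id:
                raise ValidationError(f"duplicate gene id {g.gene_id!r}")
            by_id[g.gene_id] = g
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda g: (g.start, g.end))
            for a, b in zip(recs, recs[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"overlapping genes on {chrom}: {a.gene_id} and {b.gene_id}"
                    )
        self._by_chrom = {c: tuple(v) for c, v in sorted(by_chrom.items())}
        self._by_id = by_id
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths is not None else None
        if self.chrom_lengths is not None:
            for chrom, recs in self._by_chrom.items():
                if chrom not in self.chrom_lengths:
                    raise ValidationError(f"no length given for chromosome {chrom}")
                if recs and recs[-1].end > self.chrom_lengths[chrom]:
                    raise ValidationError(
                        f"gene {recs[-1].gene_id} exceeds {chrom} length"
                    )

    # -- access ------------------------------------------------------------

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._by_chrom)

    def genes(self, chrom: str | None = None) -> tuple[Gene, ...]:
        if chrom is not None:
            return self._by_chrom.get(chrom, ())
        return tuple(g for c in self._by_chrom for g in self._by_chrom[c])

    def get(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneAnnotation):
            return NotImplemented
        return (
            self._by_chrom == other._by_chrom
            and self.chrom_lengths == other.chrom_lengths
        )

    def subset(self, gene_ids: Iterable[str]) -> "GeneAnnotation":
        keep = set(gene_ids)
        return GeneAnnotation(
            (g for g in self if g.gene_id in keep), self.chrom_lengths
        )

    # -- neighborhood ------------------------------------------------------

    def intergenic_gaps(self) -> dict[str, tuple[float, float]]:
        """Strand-aware (upstream_IG, downstream_IG) in bp for every gene.

        The gap is measured to the nearest neighboring gene boundary on the
        same chromosome regardless of the neighbor's strand; first/last
        genes use the distance to the chromosome edge, or ``inf`` when the
        chromosome length is unknown.
        """
        out: dict[str, tuple[float, float]] = {}
        for chrom, recs in self._by_chrom.items():
            if self.chrom_lengths is not None:
                clen: float = self.chrom_lengths[chrom]
            else:
                clen = math.inf
            for i, g in enumerate(recs):
                left = float(g.start - (recs[i - 1].end if i > 0 else 0))
                right = (recs[i + 1].start if i + 1 < len(recs) else clen) - g.end
                right = float(right)
                if g.strand == "+":
                    out[g.gene_id] = (left, right)
                else:
                    out[g.gene_id] = (right, left)
        return out


# ---------------------------------------------------------------------------
# Probe tracks
# ---------------------------------------------------------------------------

def _validate_probe_arrays(
    chrom: str, starts: np.ndarray, ends: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    values = np.asarray(values, dtype=np.float64)
    if not (starts.shape == ends.shape == values.shape):
        raise ValidationError(f"{chrom}: probe arrays have mismatched shapes")
    if starts.size:
        if np.any(ends <= starts):
            raise ValidationError(f"{chrom}: empty or inverted probe interval")
        if np.any(starts[1:] < starts[:-1]):
            raise ValidationError(f"{chrom}: probes not sorted by start")
        if np.any(starts[1:] < ends[:-1]):
            raise ValidationError(f"{chrom}: overlapping probes")
        if np.any(np.isinf(values)):
            raise ValidationError(f"{chrom}: infinite probe value")
    return starts, ends, values


class ProbeTrack:
    """Sorted, non-overlapping probe intervals with one value per probe.

    ``data`` maps chromosome name to ``(starts, ends, values)`` arrays.
    Values are float64; NaN marks a missing measurement.
    """

    def __init__(
        self,
        experiment_id: str,
        data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> None:
        self.experiment_id = experiment_id
        self._data = {
            chrom: _validate_probe_arrays(chrom, *arrs)
            for chrom, arrs in sorted(data.items())
        }

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._data)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._data[chrom]

    def items(self) -> Iterator[tuple[str, tuple[np.ndarray, np.ndarray, np.ndarray]]]:
        return iter(self._data.items())

    def midpoints(self, chrom: str) -> np.ndarray:
        starts, ends, _ = self._data[chrom]
        return (starts + ends) / 2.0

    @property
    def n_probes(self) -> int:
        return sum(s.size for s, _, _ in self._data.values())

    def all_values(self) -> np.ndarray:
        """All probe values concatenated in chromosome order (NaN included)."""
        parts = [v for _, _, v in self._data.values()]
        return np.concatenate(parts) if parts else np.empty(0)

    def same_grid(self, other: "ProbeTrack") -> bool:
        if self.chromosomes != other.chromosomes:
            return False
        for chrom in self.chromosomes:
            s1, e1, _ = self._data[chrom]
            s2, e2, _ = other.arrays(chrom)
            if s1.shape != s2.shape or np.any(s1 != s2) or np.any(e1 != e2):
                return False
        return True

    def with_values(
        self, values: Mapping[str, np.ndarray], experiment_id: str | None = None
    ) -> "ProbeTrack":
        """Same grid, new per-chromosome value arrays."""
        data = {
            chrom: (s, e, np.asarray(values[chrom], dtype=np.float64))
            for chrom, (s, e, _) in self._data.items()
        }
        return ProbeTrack(experiment_id or self.experiment_id, data)


class ZScoreTrack(ProbeTrack):
    """A probe track whose non-missing values are standardized.

    Invariant: mean 0 and population standard deviation 1 over the
    non-missing probes, to within 1e-9.
    """

    _TOL = 1e-9

    def __init__(self, experiment_id, data) -> None:
        super().__init__(experiment_id, data)
        vals = self.all_values()
        finite = vals[~np.isnan(vals)]
        if finite.size < 2:
            raise ValidationError("Z-score track needs >=2 non-missing probes")
        mean = float(np.mean(finite))
        sd = float(np.std(finite))
        if abs(mean) > self._TOL or abs(sd - 1.0) > self._TOL:
            raise ValidationError(
                f"not standardized: mean={mean:.3g}, sd={sd:.6g}"
            )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _infer_annotation_format(path: str | Path) -> str:
    name = Path(path).name.removesuffix(".gz")
    if name.endswith((".gff3", ".gff")):
        return "gff3"
    if name.endswith(".bed"):
        return "bed"
    raise ValidationError(f"cannot infer annotation format from {name!r}")


_GFF_GENE_TYPES = {"gene", "protein_coding_gene"}


def read_annotation(path: str | Path, format: str | None = None) -> GeneAnnotation:
    """Read a gene annotation from GFF3 (1-based inclusive) or BED6.

    GFF3 starts are shifted by -1 into the internal 0-based half-open
    convention; BED coordinates are used as-is.  For GFF3 only gene-typed
    records are retained and ``##sequence-region`` pragmas provide
    chromosome lengths.  Overlapping genes raise :class:`ValidationError`.
    """
    fmt = format or _infer_annotation_format(path)
    if fmt not in ("gff3", "bed"):
        raise ValidationError(f"unknown annotation format {fmt!r}")
    genes: list[Gene] = []
    chrom_lengths: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if fmt == "gff3" and line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "gff3":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated fields")
                    if fields[2] not in _GFF_GENE_TYPES:
                        continue
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    gene_id = attrs.get("ID") or attrs.get("Name")
                    if gene_id is None:
                        raise ValueError("gene record without ID attribute")
                    genes.append(
                        Gene(gene_id, fields[0], int(fields[3]) - 1, int(fields[4]),
                             fields[6])
                    )
                else:
                    if len(fields) < 6:
                        raise ValueError("expected 6 tab-separated fields")
                    genes.append(
                        Gene(fields[3], fields[0], int(fields[1]), int(fields[2]),
                             fields[5])
                    )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return GeneAnnotation(genes, chrom_lengths or None)


def write_annotation(
    annotation: GeneAnnotation, path: str | Path, format: str | None = None
) -> None:
    """Write GFF3 (with ``##sequence-region`` pragmas) or BED6."""
    fmt = format or _infer_annotation_format(path)
    with _open_text(path, "wt") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            if annotation.chrom_lengths:
                for chrom, length in sorted(annotation.chrom_lengths.items()):
                    fh.write(f"##sequence-region {chrom} 1 {length}\n")
            for g in annotation:
                fh.write(
                    f"{g.chrom}\tchiptile\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
        elif fmt == "bed":
            for g in annotation:
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
                )
        else:
            raise ValidationError(f"unknown annotation format {fmt!r}")


def read_track(path: str | Path, experiment_id: str | None = None) -> ProbeTrack:
    """Read a 4-column bedGraph into a :class:`ProbeTrack`.

    Probes absent from the file are simply absent from the track (they were
    missing when written).  Unsorted or overlapping intervals are rejected.
    """
    by_chrom: dict[str, tuple[list[int], list[int], list[float]]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                chrom, start, end, value = (
                    fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            s, e, v = by_chrom.setdefault(chrom, ([], [], []))
            s.append(start)
            e.append(end)
            v.append(value)
    exp_id = experiment_id or Path(path).name.removesuffix(".gz").rsplit(".", 1)[0]
    data = {
        chrom: (np.array(s, dtype=np.int64), np.array(e, dtype=np.int64),
                np.array(v, dtype=np.float64))
        for chrom, (s, e, v) in by_chrom.items()
    }
    return ProbeTrack(exp_id, data)


def write_track(track: ProbeTrack, path: str | Path) -> None:
    """Write a 4-column bedGraph; missing (NaN) probes are omitted.

    Values are printed with ``repr`` so the read/write round trip is exact
    for every non-missing probe.
    """
    with _open_text(path, "wt") as fh:
        for chrom, (starts, ends, values) in track.items():
            for s, e, v in zip(starts, ends, values):
                if not math.isnan(v):
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


def write_summary(table, path: str | Path) -> None:
    """Write a per-gene summary table as TSV with ``NA`` for missing values.

    Accepts any object exposing a ``df`` DataFrame attribute (or a bare
    DataFrame) indexed by gene id; the column order is preserved so output
    is stable across runs.
    """
    df = getattr(table, "df", table)
    with _open_text(path, "wt") as fh:
        # repr gives the shortest exact decimal, so reads are lossless
        df.to_csv(fh, sep="\t", na_rep="NA", index_label="gene_id",
                  float_format=lambda v: repr(float(v)))


def read_summary(path: str | Path) -> pd.DataFrame:
    with _open_text(path) as fh:
        return pd.read_csv(fh, sep="\t", index_col="gene_id", na_values=["NA"],
                           float_precision="round_trip")
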