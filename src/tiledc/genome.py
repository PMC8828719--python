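"""Genomic coordinate arithmetic, bin grids, and feature annotations.

All coordinates are 0-based half-open internally (BED convention).
Intervals published with inclusive end coordinates (e.g.
``chr16:92,496,000-93,617,999``) must be converted on ingest by adding 1
to the end; :meth:`GenomicInterval.from_inclusive` does this.

A :class:`BinGrid` partitions a single tiled region into fixed-width
bins and is the coordinate authority for every contact matrix and track
in the package.  Tiled-C assays one contiguous region, so grids are
single-chromosome by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "BinGrid",
    "Feature",
    "FeatureSet",
    "read_bed",
    "write_bed",
    "CATEGORIES",
    "ORIENTATIONS",
]

CATEGORIES = frozenset({"enhancer", "ctcf", "promoter"})
ORIENTATIONS = frozenset({"forward", "reverse", "none"})


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    @classmethod
    def from_inclusive(cls, chrom: str, start: int, end_inclusive: int) -> "GenomicInterval":
        """Build from a printed interval whose end base is inclusive."""
        return cls(chrom, start, end_inclusive + 1)

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width binning of a tiled region.

    The last bin may be shorter than ``bin_size`` when the region length
    is not a multiple of the bin size; it is a full citizen of the grid.
    """

    region: GenomicInterval
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be > 0, got {self.bin_size}")

    @property
    def chrom(self) -> str:
        return self.region.chrom

    @property
    def n_bins(self) -> int:
        return math.ceil(self.region.length / self.bin_size)

    def coord_to_bin(self, pos: int) -> int:
        """Map a base position inside the tile to its bin index."""
        if not self.region.contains(pos):
            raise ValueError(
                f"position {pos} outside tile "
                f"{self.chrom}:{self.region.start}-{self.region.end}"
            )
        return (pos - self.region.start) // self.bin_size

    def bin_interval(self, index: int) -> GenomicInterval:
        """Inverse of :meth:`coord_to_bin`: the interval a bin covers."""
        if not 0 <= index < self.n_bins:
            raise IndexError(f"bin {index} not in [0, {self.n_bins})")
        start = self.region.start + index * self.bin_size
        end = min(start + self.bin_size, self.region.end)
        return GenomicInterval(self.chrom, start, end)

    def bins_for_interval(self, iv: GenomicInterval) -> range:
        """Half-open range of bin indices overlapping ``iv``."""
        if not self.region.overlaps(iv):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} does not overlap tile "
                f"{self.chrom}:{self.region.start}-{self.region.end}"
            )
        first = self.coord_to_bin(max(iv.start, self.region.start))
        last = self.coord_to_bin(min(iv.end, self.region.end) - 1)
        return range(first, last + 1)

    # -- sidecar serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "start": self.region.start,
            "end": self.region.end,
            "bin_size": self.bin_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinGrid":
        return cls(GenomicInterval(d["chrom"], d["start"], d["end"]), d["bin_size"])

    def write_sidecar(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def read_sidecar(cls, path: str | Path) -> "BinGrid":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Feature:
    """A named annotation (enhancer, CTCF site, or promoter).

    ``orientation`` records CTCF motif orientation and must be ``none``
    for any other category.
    """

    name: str
    interval: GenomicInterval
    category: str
    orientation: str = "none"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not in {sorted(CATEGORIES)}"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"orientation {self.orientation!r} not in {sorted(ORIENTATIONS)}"
            )
        if self.category != "ctcf" and self.orientation != "none":
            raise ValueError(
                f"orientation must be 'none' for category {self.category!r}"
            )


@dataclass
class FeatureSet:
    """Ordered collection of features with a free-text provenance tag."""

    features: list[Feature] = field(default_factory=list)
    provenance: str = ""

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def of_category(self, category: str) -> "FeatureSet":
        return FeatureSet(
            [f for f in self.features if f.category == category],
            provenance=self.provenance,
        )

    def by_name(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


_STRAND_TO_ORIENT = {"+": "forward", "-": "reverse", ".": "none"}
_ORIENT_TO_STRAND = {v: k for k, v in _STRAND_TO_ORIENT.items()}


def read_bed(path: str | Path, category: str, provenance: str | None = None) -> FeatureSet:
    """Read a 3-6 column BED file into a :class:`FeatureSet`.

    BED carries no feature class, so the caller assigns one ``category``
    to every record (one BED file per annotation class).  Column 4 is
    the name and column 6 the strand; strand maps to motif orientation
    for CTCF features and is ignored otherwise.
    """
    path = Path(path)
    features: list[Feature] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        try:
            iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else f"feature_{lineno}"
        orientation = "none"
        if category == "ctcf" and len(cols) > 5:
            try:
                orientation = _STRAND_TO_ORIENT[cols[5]]
            except KeyError:
                raise ValueError(f"{path}:{lineno}: bad strand {cols[5]!r}") from None
        features.append(Feature(name, iv, category, orientation))
    return FeatureSet(features, provenance=provenance or str(path))


def write_bed(fs: FeatureSet, path: str | Path) -> None:
    """Write features as 6-column BED (score column fixed at 0)."""
    lines = []
    for f in fs:
        strand = _ORIENT_TO_STRAND[f.orientation]
        lines.append(
            f"{f.interval.chrom}\t{f.interval.start}\t{f.interval.end}"
            f"\t{f.name}\t0\t{strand}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
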