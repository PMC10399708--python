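"""Genome coordinate model: chromosomes, centromeres, arms and windowing.

All coordinates are 0-based, half-open.  A :class:`GenomeBuild` carries the
chromosome lengths and centromere intervals that anchor the arm and
sub-telomere notions used by the scar definitions (telomeric allelic
imbalance must not cross the centromere; large-scale transitions are
assessed per arm).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GenomicInterval",
    "GenomeBuild",
    "load_genome",
    "grch37",
    "toy_genome",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

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


@dataclass
class GenomeBuild:
    """Chromosome lengths plus per-chromosome centromere intervals.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length)`` pairs.
    centromeres:
        Mapping ``name -> (cen_start, cen_end)``; each interval must lie
        strictly inside its chromosome.
    name:
        Free-text build label (e.g. ``"GRCh37"``).
    """

    chromosomes: list[tuple[str, int]]
    centromeres: dict[str, tuple[int, int]]
    name: str = "custom"
    _lengths: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome build")
        self._lengths = dict(self.chromosomes)
        for chrom, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            if chrom not in self.centromeres:
                raise ValueError(f"chromosome {chrom} lacks a centromere interval")
            cs, ce = self.centromeres[chrom]
            if not (0 < cs < ce < length):
                raise ValueError(
                    f"centromere [{cs}, {ce}) of {chrom} not strictly inside "
                    f"chromosome of length {length}"
                )

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r} in build {self.name}") from None

    def centromere(self, chrom: str) -> GenomicInterval:
        self.length_of(chrom)
        cs, ce = self.centromeres[chrom]
        return GenomicInterval(chrom, cs, ce)

    def arm_of(self, interval: GenomicInterval) -> str:
        """Classify an interval as ``"p"``, ``"q"`` or ``"spans-centromere"``.

        The p arm is everything left of the centromere interval, the q arm
        everything right of it; an interval overlapping the centromere
        interval itself is ``"spans-centromere"``.
        """
        length = self.length_of(interval.chrom)
        if interval.end > length or interval.start < 0:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {length}"
            )
        cs, ce = self.centromeres[interval.chrom]
        if interval.end <= cs:
            return "p"
        if interval.start >= ce:
            return "q"
        return "spans-centromere"

    def tile_windows(self, width: int, chrom: str | None = None) -> list[GenomicInterval]:
        """Tile chromosomes into consecutive non-overlapping windows.

        The last window of each chromosome may be shorter than ``width``.
        """
        if width <= 0:
            raise ValueError("window width must be positive")
        chroms = [chrom] if chrom is not None else self.chrom_names
        windows: list[GenomicInterval] = []
        for c in chroms:
            length = self.length_of(c)
            for start in range(0, length, width):
                windows.append(GenomicInterval(c, start, min(start + width, length)))
        return windows

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": c,
                "length": l,
                "cen_start": self.centromeres[c][0],
                "cen_end": self.centromeres[c][1],
            }
            for c, l in self.chromosomes
        ]
        return pd.DataFrame(rows)


def arm_of(interval: GenomicInterval, genome: GenomeBuild) -> str:
    """Functional alias for :meth:`GenomeBuild.arm_of`."""
    return genome.arm_of(interval)


def tile_windows(genome: GenomeBuild, width: int) -> list[GenomicInterval]:
    """Functional alias for :meth:`GenomeBuild.tile_windows`."""
    return genome.tile_windows(width)


def load_genome(path, name: str | None = None) -> GenomeBuild:
    """Read a genome build from a TSV with columns chrom/length/cen_start/cen_end."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "length", "cen_start", "cen_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genome file {path} missing columns: {sorted(missing)}")
    chromosomes = [(str(r.chrom), int(r.length)) for r in df.itertuples()]
    centromeres = {
        str(r.chrom): (int(r.cen_start), int(r.cen_end)) for r in df.itertuples()
    }
    return GenomeBuild(chromosomes, centromeres, name=name or str(path))


def grch37(include_sex: bool = True) -> GenomeBuild:
    """The packaged GRCh37 build (UCSC hg19 centromere gap coordinates)."""
    ref = importlib.resources.files("hrdscar.data") / "grch37.genome.tsv"
    with importlib.resources.as_file(ref) as path:
        build = load_genome(path, name="GRCh37")
    if not include_sex:
        autosomes = [(c, l) for c, l in build.chromosomes if c not in ("chrX", "chrY")]
        cen = {c: build.centromeres[c] for c, _ in autosomes}
        build = GenomeBuild(autosomes, cen, name="GRCh37-autosomes")
    return build


def toy_genome(n_chrom: int = 3, length: int = 100_000_000) -> GenomeBuild:
    """A small test genome: ``n_chrom`` metacentric chromosomes of equal length.

    Centromeres sit at the middle 3% of each chromosome, leaving two arms of
    roughly ``length/2`` each — large enough to host >15 Mb LOH segments and
    11 Mb transition blocks at desk scale.
    """
    half = length // 2
    cen_half = max(length // 66, 1)
    chromosomes = [(f"chr{i + 1}", length) for i in range(n_chrom)]
    centromeres = {c: (half - cen_half, half + cen_half) for c, _ in chromosomes}
    return GenomeBuild(chromosomes, centromeres, name="toy")
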