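"""Genomic scar scores: HRD-LOH, HRD-TAI, HRD-LST and their sum.

Definitions (counts over a smoothed allele-specific copy-number profile):

* **HRD-LOH** — segments with complete loss of one allele (``nB = 0``,
  ``nA >= 1``) longer than 15 Mb but shorter than the whole chromosome.
* **HRD-TAI** — maximal runs of allelic imbalance (``nA != nB``) that reach
  a sub-telomere (the first or last covered base of the chromosome) and do
  not overlap the centromere.
* **HRD-LST** — breakpoints between adjacent copy-number states where both
  flanking regions, clipped to the chromosome arm, span at least 11 Mb;
  breaks falling in the centromere are not counted.  Counting follows a
  smoothing pass that removes all segments shorter than 3 Mb.

The HRD score is the plain sum of the three; samples at or above the
clinical cutoff (42) are called HRD-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ascn import ASCNProfile, Segment
from .genome_model import GenomeBuild

__all__ = [
    "ScarConfig",
    "ScarScores",
    "normalize_profile",
    "count_hrd_loh",
    "count_tai",
    "count_lst",
    "score_hrd",
    "HRD_CUTOFF",
]

HRD_CUTOFF = 42
SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass(frozen=True)
class ScarConfig:
    """Tunable thresholds of the three scar definitions (bp units)."""

    loh_min_size: int = 15_000_000  # strict: segments must exceed this
    lst_min_segment: int = 11_000_000  # inclusive: flanks of at least this
    smooth_below: int = 3_000_000  # strict: segments under this are smoothed
    min_tai_size: int = 0
    include_sex: bool = False


@dataclass(frozen=True)
class ScarScores:
    """The (LOH, TAI, LST) triple, their sum, and the binary HRD call."""

    loh: int
    tai: int
    lst: int
    cutoff: int = HRD_CUTOFF

    def __post_init__(self) -> None:
        if min(self.loh, self.tai, self.lst) < 0:
            raise ValueError("scar counts must be non-negative")

    @property
    def hrd(self) -> int:
        return self.loh + self.tai + self.lst

    @property
    def positive(self) -> bool:
        return self.hrd >= self.cutoff

    @property
    def status(self) -> str:
        return "positive" if self.positive else "negative"

    def as_dict(self) -> dict:
        return {
            "loh": self.loh,
            "tai": self.tai,
            "lst": self.lst,
            "hrd": self.hrd,
            "status": self.status,
            "cutoff": self.cutoff,
        }


def _as_segments(profile) -> list[Segment]:
    if isinstance(profile, ASCNProfile):
        return profile.segments
    return list(profile)


def _by_chrom(segments: list[Segment]) -> dict[str, list[Segment]]:
    out: dict[str, list[Segment]] = {}
    for seg in segments:
        if seg.nA is None:
            raise ValueError("scar scoring requires assigned (nA, nB) states")
        out.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in out.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                )
    return out


def _merge_equal(segs: list[Segment]) -> list[Segment]:
    """Merge touching segments with identical (nA, nB)."""
    merged: list[Segment] = []
    for seg in segs:
        if (
            merged
            and merged[-1].end == seg.start
            and merged[-1].state == seg.state
        ):
            prev = merged[-1]
            merged[-1] = Segment(
                prev.chrom, prev.start, seg.end,
                n_sites=prev.n_sites + seg.n_sites,
                nA=prev.nA, nB=prev.nB,
            )
        else:
            merged.append(seg)
    return merged


def _smooth_chrom(segs: list[Segment], smooth_below: int) -> list[Segment]:
    segs = _merge_equal(segs)
    while segs:
        short = [s for s in segs if s.length < smooth_below]
        if not short:
            return segs
        if len(segs) == 1:
            return []  # a lone sub-threshold segment disappears
        victim = min(short, key=lambda s: (s.length, s.start))
        i = segs.index(victim)
        left = segs[i - 1] if i > 0 and segs[i - 1].end == victim.start else None
        right = (
            segs[i + 1]
            if i + 1 < len(segs) and segs[i + 1].start == victim.end
            else None
        )
        if left is not None and right is not None and left.state == right.state:
            fused = Segment(
                left.chrom, left.start, right.end,
                n_sites=left.n_sites + right.n_sites,
                nA=left.nA, nB=left.nB,
            )
            segs = segs[: i - 1] + [fused] + segs[i + 2 :]
        elif left is not None and right is not None:
            mid = (victim.start + victim.end) // 2
            new_left = Segment(
                left.chrom, left.start, mid, n_sites=left.n_sites,
                nA=left.nA, nB=left.nB,
            )
            new_right = Segment(
                right.chrom, mid, right.end, n_sites=right.n_sites,
                nA=right.nA, nB=right.nB,
            )
            segs = segs[: i - 1] + [new_left, new_right] + segs[i + 2 :]
        elif left is not None:
            segs = segs[: i - 1] + [
                Segment(left.chrom, left.start, victim.end,
                        n_sites=left.n_sites, nA=left.nA, nB=left.nB)
            ] + segs[i + 1 :]
        elif right is not None:
            segs = segs[:i] + [
                Segment(right.chrom, victim.start, right.end,
                        n_sites=right.n_sites, nA=right.nA, nB=right.nB)
            ] + segs[i + 2 :]
        else:
            # isolated short segment (uncovered on both sides): drop it
            segs = segs[:i] + segs[i + 1 :]
        segs = _merge_equal(segs)
    return segs


def normalize_profile(
    profile, config: ScarConfig | None = None
) -> list[Segment]:
    """Merge equal neighbours and smooth away segments shorter than 3 Mb.

    Iteratively removes the shortest sub-threshold segment, absorbing its
    interval into the flanks (equal flanks fuse across it; unequal flanks
    each extend to its midpoint), re-merging until a fixpoint.  Idempotent.
    """
    config = config or ScarConfig()
    out: list[Segment] = []
    for _, segs in sorted(_by_chrom(_as_segments(profile)).items()):
        out.extend(_smooth_chrom(segs, config.smooth_below))
    return out


def _scored_chroms(profile, config: ScarConfig) -> dict[str, list[Segment]]:
    chroms = _by_chrom(_as_segments(profile))
    if not config.include_sex:
        chroms = {c: s for c, s in chroms.items() if c not in SEX_CHROMS}
    return chroms


def count_hrd_loh(profile, genome: GenomeBuild, config: ScarConfig | None = None) -> int:
    """Count LOH segments > 15 Mb that do not span their whole chromosome."""
    config = config or ScarConfig()
    n = 0
    for chrom, segs in _scored_chroms(profile, config).items():
        covered_start = min(s.start for s in segs)
        covered_end = max(s.end for s in segs)
        for s in segs:
            if (
                s.nB == 0
                and s.nA >= 1
                and s.length > config.loh_min_size
                and not (s.start == covered_start and s.end == covered_end)
            ):
                n += 1
    return n


def count_tai(profile, genome: GenomeBuild, config: ScarConfig | None = None) -> int:
    """Count telomeric allelic-imbalance regions.

    A maximal run of touching segments with ``nA != nB`` counts if it reaches
    the first or last covered base of its chromosome and its interval does
    not overlap the centromere.
    """
    config = config or ScarConfig()
    n = 0
    for chrom, segs in _scored_chroms(profile, config).items():
        cen = genome.centromere(chrom)
        covered_start = min(s.start for s in segs)
        covered_end = max(s.end for s in segs)
        runs: list[tuple[int, int]] = []
        cur: tuple[int, int] | None = None
        prev_end = None
        for s in segs:
            imbalanced = s.nA != s.nB
            if imbalanced:
                if cur is not None and prev_end == s.start:
                    cur = (cur[0], s.end)
                else:
                    if cur is not None:
                        runs.append(cur)
                    cur = (s.start, s.end)
            else:
                if cur is not None:
                    runs.append(cur)
                    cur = None
            prev_end = s.end
        if cur is not None:
            runs.append(cur)
        for start, end in runs:
            touches_telomere = start == covered_start or end == covered_end
            crosses_cen = start < cen.end and end > cen.start
            if (
                touches_telomere
                and not crosses_cen
                and end - start >= config.min_tai_size
            ):
                n += 1
    return n


def _arm_parts(
    segs: list[Segment], cen_start: int, cen_end: int
) -> tuple[list[tuple[int, int, tuple[int, int]]], list[tuple[int, int, tuple[int, int]]]]:
    """Clip segments to the p and q arms; parts keep their copy state."""
    p_parts, q_parts = [], []
    for s in segs:
        if s.start < cen_start:
            p_parts.append((s.start, min(s.end, cen_start), s.state))
        if s.end > cen_end:
            q_parts.append((max(s.start, cen_end), s.end, s.state))
    return p_parts, q_parts


def count_lst(profile, genome: GenomeBuild, config: ScarConfig | None = None) -> int:
    """Count large-scale transitions on an (already smoothed) profile.

    Per arm, a break between touching parts with different states counts when
    both parts are at least 11 Mb after clipping to the arm; breaks inside
    the centromere vanish with the clipping.
    """
    config = config or ScarConfig()
    n = 0
    for chrom, segs in _scored_chroms(profile, config).items():
        cen = genome.centromere(chrom)
        for parts in _arm_parts(segs, cen.start, cen.end):
            for (s1, e1, st1), (s2, e2, st2) in zip(parts, parts[1:]):
                if (
                    e1 == s2
                    and st1 != st2
                    and e1 - s1 >= config.lst_min_segment
                    and e2 - s2 >= config.lst_min_segment
                ):
                    n += 1
    return n


def score_hrd(
    profile,
    genome: GenomeBuild,
    cutoff: int = HRD_CUTOFF,
    config: ScarConfig | None = None,
    normalize: bool = True,
) -> ScarScores:
    """Compute (LOH, TAI, LST), their sum, and the HRD call at ``cutoff``.

    ``normalize=True`` (default) applies the 3-Mb smoothing first; it is
    idempotent, so passing an already-normalised profile is harmless.
    """
    config = config or ScarConfig()
    segs = normalize_profile(profile, config) if normalize else _as_segments(profile)
    return ScarScores(
        loh=count_hrd_loh(segs, genome, config),
        tai=count_tai(segs, genome, config),
        lst=count_lst(segs, genome, config),
        cutoff=cutoff,
    )
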