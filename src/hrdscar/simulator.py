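"""Synthetic tumors with planted genomic-scar events.

The generator lays out piecewise-constant allele-specific copy-number
genomes on a diploid ``(1, 1)`` background and plants three event classes,
one chromosome arm per LOH/TAI event and chains of large blocks for LST:

* **LOH** — a ``(1, 0)`` segment filling an arm up to a short (3.5-10.5 Mb)
  telomeric remainder, so the segment exceeds 15 Mb, never spans the whole
  chromosome, and its single internal breakpoint has a sub-11 Mb flank.
* **TAI** — a ``(2, 1)`` segment from the telomere toward the centromere,
  leaving a sub-11 Mb balanced remainder before the centromere.
* **LST** — an arm tiled by alternating ``(1, 1)`` / ``(2, 2)`` blocks, all
  at least 11 Mb; ``k + 1`` blocks plant exactly ``k`` transitions.
* **decoys** — sub-3 Mb aberrant blips inside diploid arms that the 3-Mb
  smoothing must erase.

The geometry makes every planted event score exactly once and nothing else
score at all, so the planted ledger *is* the expected (LOH, TAI, LST)
triple — the generator/scorer round trip is exact by construction.

Observations are allele read counts at panel SNPs under the purity mixture:
normal genotypes are Hardy-Weinberg draws from the SNP's population allele
frequency, depths are Poisson, and tumor allele counts are binomial at the
mixture's expected B-allele fraction with random allele orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ascn import Segment, expected_baf, expected_depth_ratio
from .genome_model import GenomeBuild
from .panel_design import DesignConfig, PanelDesign, SNPCandidate
from .scar_scores import SEX_CHROMS

__all__ = [
    "EventSpec",
    "TruthProfile",
    "SiteObservation",
    "simulate_truth_profile",
    "diploid_profile",
    "synthetic_panel",
    "draw_genotypes",
    "simulate_observations",
    "mix_purity",
    "downsample_depth",
]

OBS_COLUMNS = ["chrom", "pos", "n_ref", "n_alt", "t_ref", "t_alt", "normal_gt"]

_MB = 1_000_000


@dataclass(frozen=True)
class SiteObservation:
    """One SNP's tumor and normal allele depths (normal_gt: 0 hom-ref,
    1 het, 2 hom-alt)."""

    chrom: str
    pos: int
    n_ref: int
    n_alt: int
    t_ref: int
    t_alt: int
    normal_gt: int


@dataclass(frozen=True)
class EventSpec:
    """Counts and size ranges of planted scar events (sizes in bp).

    Defaults model a moderately scarred tumor; :meth:`scar_rich` and
    :meth:`near_diploid` give the two reference conditions (clearly above
    and far below the clinical cutoff of 42) used throughout the
    dilution/depth/panel experiments.
    """

    n_loh: int = 5
    n_tai: int = 5
    n_lst: int = 5
    n_decoy: int = 5
    loh_min_size: int = 16 * _MB
    tai_min_size: int = 15 * _MB
    lst_block_min: int = 12 * _MB
    remainder_range: tuple[int, int] = (3_500_000, 10_500_000)
    decoy_size_range: tuple[int, int] = (500_000, 2_500_000)
    mean_depth: float = 300.0
    snp_spacing: int = 50_000

    def __post_init__(self) -> None:
        if min(self.n_loh, self.n_tai, self.n_lst, self.n_decoy) < 0:
            raise ValueError("event counts must be non-negative")
        if min(self.loh_min_size, self.tai_min_size, self.lst_block_min) <= 0:
            raise ValueError("event sizes must be positive")

    @classmethod
    def scar_rich(cls, **kw) -> "EventSpec":
        """A high-HRD tumor: planted ledger sums to 50, above the cutoff."""
        return cls(n_loh=12, n_tai=12, n_lst=26, n_decoy=8, **kw)

    @classmethod
    def near_diploid(cls, **kw) -> "EventSpec":
        """A low-HRD, near-diploid tumor (ledger sums to 3)."""
        return cls(n_loh=1, n_tai=1, n_lst=1, n_decoy=6, **kw)


@dataclass
class TruthProfile:
    """Ground-truth tumor genome: purity, ploidy, segments, planted ledger."""

    purity: float
    ploidy: float
    segments: list[Segment]
    ledger: dict[str, int]
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError(f"purity {self.purity} outside (0, 1]")
        by_chrom: dict[str, list[Segment]] = {}
        for s in self.segments:
            if s.nA is None or not (s.nA >= s.nB >= 0):
                raise ValueError("truth segments need nA >= nB >= 0")
            by_chrom.setdefault(s.chrom, []).append(s)
        for segs in by_chrom.values():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if a.end != b.start:
                    raise ValueError(
                        f"truth segments must tile {a.chrom}: gap/overlap at {a.end}"
                    )


def _mean_cn(segments: list[Segment]) -> float:
    num = sum(s.length * (s.nA + s.nB) for s in segments)
    den = sum(s.length for s in segments)
    return num / den


def _arms(genome: GenomeBuild) -> list[tuple[str, int, int, str]]:
    arms = []
    for chrom, length in genome.chromosomes:
        if chrom in SEX_CHROMS:
            continue
        cs, ce = genome.centromeres[chrom]
        arms.append((chrom, 0, cs, "p"))
        arms.append((chrom, ce, length, "q"))
    return arms


def _uniform_int(rng: np.random.Generator, low: int, high: int) -> int:
    return int(rng.integers(low, max(high, low) + 1))


def simulate_truth_profile(
    genome: GenomeBuild,
    spec: EventSpec,
    seed: int,
    purity: float = 1.0,
) -> TruthProfile:
    """Plant the requested events on a diploid background.

    Each LOH/TAI event claims one chromosome arm, each LST arm hosts a chain
    of blocks planting several transitions, and decoys go to leftover arms.
    Raises ``ValueError`` naming the event class that does not fit.
    """
    rng = np.random.default_rng(seed)
    rem_lo, rem_hi = spec.remainder_range
    if not (0 < rem_lo < rem_hi < spec.lst_block_min):
        raise ValueError("remainder range must lie strictly below the LST block size")

    arms = _arms(genome)
    order = rng.permutation(len(arms))
    free = [arms[i] for i in order]

    # (chrom, arm-side) -> list of (start, end, nA, nB) event pieces
    pieces: dict[tuple[str, str], list[tuple[int, int, int, int]]] = {}

    def arm_len(arm):
        return arm[2] - arm[1]

    def telomere_anchor(arm, size):
        """Interval of `size` bp anchored at the arm's telomeric end."""
        chrom, start, end, side = arm
        return (start, start + size) if side == "p" else (end - size, end)

    # --- LST arms: chains of alternating (1,1)/(2,2) blocks
    remaining_lst = spec.n_lst
    while remaining_lst > 0:
        candidates = [a for a in free if arm_len(a) >= 2 * spec.lst_block_min]
        if not candidates:
            raise ValueError(
                f"cannot place {remaining_lst} remaining LST event(s): "
                "no free arm can host two 11 Mb blocks"
            )
        arm = candidates[0]
        free.remove(arm)
        capacity = arm_len(arm) // spec.lst_block_min - 1
        k = int(min(remaining_lst, capacity))
        n_blocks = k + 1
        extra = arm_len(arm) - n_blocks * spec.lst_block_min
        shares = rng.dirichlet(np.ones(n_blocks)) * extra
        sizes = (spec.lst_block_min + shares).astype(int)
        sizes[-1] += arm_len(arm) - int(sizes.sum())
        first_dup = int(rng.integers(0, 2))  # chain may start (1,1) or (2,2)
        chrom, start, end, side = arm
        pos = start
        plist = []
        for i, size in enumerate(sizes):
            cn = 1 if (i + first_dup) % 2 == 0 else 2
            plist.append((pos, pos + size, cn, cn))
            pos += size
        pieces[(chrom, side)] = plist
        remaining_lst -= k

    # --- TAI arms: telomeric (2,1) with a short balanced remainder
    min_tai_arm = spec.tai_min_size + rem_lo
    for i in range(spec.n_tai):
        candidates = [a for a in free if arm_len(a) >= min_tai_arm]
        if not candidates:
            raise ValueError(f"cannot place TAI event {i + 1} of {spec.n_tai}")
        arm = candidates[0]
        free.remove(arm)
        gap = min(_uniform_int(rng, rem_lo, rem_hi), arm_len(arm) - spec.tai_min_size)
        s, e = telomere_anchor(arm, arm_len(arm) - gap)
        pieces[(arm[0], arm[3])] = [(s, e, 2, 1)]

    # --- LOH arms: centromere-anchored (1,0) with a short telomeric remainder
    min_loh_arm = spec.loh_min_size + rem_lo
    for i in range(spec.n_loh):
        candidates = [a for a in free if arm_len(a) >= min_loh_arm]
        if not candidates:
            raise ValueError(f"cannot place LOH event {i + 1} of {spec.n_loh}")
        arm = candidates[0]
        free.remove(arm)
        gap = min(_uniform_int(rng, rem_lo, rem_hi), arm_len(arm) - spec.loh_min_size)
        chrom, start, end, side = arm
        if side == "p":
            pieces[(chrom, side)] = [(start + gap, end, 1, 0)]
        else:
            pieces[(chrom, side)] = [(start, end - gap, 1, 0)]

    # --- decoys on leftover arms, with margins so smoothing erases them
    decoy_states = [(2, 1), (3, 1), (2, 0), (2, 2)]
    margin = 3_500_000
    decoy_arms = [a for a in free if arm_len(a) >= spec.decoy_size_range[1] + 2 * margin]
    if spec.n_decoy and not decoy_arms:
        raise ValueError(f"cannot place {spec.n_decoy} decoy segment(s): no free arm")
    cursors = {(a[0], a[3]): a[1] + margin for a in decoy_arms}
    arm_index = 0
    for i in range(spec.n_decoy):
        placed = False
        for _ in range(len(decoy_arms)):
            arm = decoy_arms[arm_index % len(decoy_arms)]
            arm_index += 1
            key = (arm[0], arm[3])
            size = _uniform_int(rng, *spec.decoy_size_range)
            pos = cursors[key]
            if pos + size + margin <= arm[2]:
                a, b = decoy_states[int(rng.integers(0, len(decoy_states)))]
                pieces.setdefault(key, []).append((pos, pos + size, a, b))
                cursors[key] = pos + size + margin
                placed = True
                break
        if not placed:
            raise ValueError(f"cannot place decoy segment {i + 1} of {spec.n_decoy}")

    segments = _assemble(genome, pieces)
    ledger = {"loh": spec.n_loh, "tai": spec.n_tai, "lst": spec.n_lst}
    return TruthProfile(
        purity=purity,
        ploidy=_mean_cn(segments),
        segments=segments,
        ledger=ledger,
        seed=seed,
    )


def _assemble(
    genome: GenomeBuild,
    pieces: dict[tuple[str, str], list[tuple[int, int, int, int]]],
) -> list[Segment]:
    """Fill around the event pieces with (1,1) background, tiling each chromosome."""
    segments: list[Segment] = []
    for chrom, length in genome.chromosomes:
        events = sorted(
            pieces.get((chrom, "p"), []) + pieces.get((chrom, "q"), [])
        )
        raw: list[tuple[int, int, int, int]] = []
        pos = 0
        for s, e, a, b in events:
            if s > pos:
                raw.append((pos, s, 1, 1))
            raw.append((s, e, a, b))
            pos = e
        if pos < length:
            raw.append((pos, length, 1, 1))
        # merge touching equal states
        merged: list[list[int]] = []
        for s, e, a, b in raw:
            if merged and merged[-1][1] == s and merged[-1][2] == a and merged[-1][3] == b:
                merged[-1][1] = e
            else:
                merged.append([s, e, a, b])
        segments.extend(
            Segment(chrom, s, e, nA=a, nB=b) for s, e, a, b in merged
        )
    return segments


def diploid_profile(genome: GenomeBuild, purity: float = 1.0) -> TruthProfile:
    """A fully diploid heterozygous genome: all segments (1, 1)."""
    segments = [Segment(c, 0, l, nA=1, nB=1) for c, l in genome.chromosomes]
    return TruthProfile(
        purity=purity,
        ploidy=2.0,
        segments=segments,
        ledger={"loh": 0, "tai": 0, "lst": 0},
    )


def synthetic_panel(
    genome: GenomeBuild,
    spacing: int = 50_000,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.15, 0.5),
) -> PanelDesign:
    """An idealised spaced SNP panel: one common SNP per spacing window.

    Ranking-population MAFs are drawn high (as the max-MAF selection rule
    produces); positions are jittered within windows.
    """
    rng = np.random.default_rng(seed)
    config = DesignConfig(spacing=spacing)
    snps: list[SNPCandidate] = []
    for chrom, length in genome.chromosomes:
        for start in range(0, length, spacing):
            end = min(start + spacing, length)
            if end - start < 2:
                continue
            pos = int(rng.integers(start, end))
            maf_rank = float(rng.uniform(*maf_range))
            maf = {
                pop: (maf_rank if pop == config.ranking_population
                      else float(rng.uniform(0.05, 0.5)))
                for pop in config.populations
            }
            counts = _hwe_counts(maf_rank, 500)
            snps.append(
                SNPCandidate(
                    chrom, pos, "A", "G",
                    maf=maf,
                    genotype_counts={p: counts for p in config.populations},
                    gc=float(rng.uniform(0.3, 0.7)),
                )
            )
    snps.sort(key=lambda s: (s.chrom, s.pos))
    return PanelDesign(snps, spacing, config)


def _hwe_counts(f: float, n: int) -> tuple[int, int, int]:
    het = round(2 * f * (1 - f) * n)
    hom_alt = round(f * f * n)
    return (n - het - hom_alt, het, hom_alt)


def draw_genotypes(panel: PanelDesign, seed: int) -> np.ndarray:
    """Hardy-Weinberg germline genotypes (0/1/2) from each SNP's ranking MAF."""
    rng = np.random.default_rng(seed)
    f = np.array([s.maf[panel.config.ranking_population] for s in panel.snps])
    u = rng.random(len(f))
    p_hom_ref = (1 - f) ** 2
    p_het = 2 * f * (1 - f)
    return np.where(u < p_hom_ref, 0, np.where(u < p_hom_ref + p_het, 1, 2)).astype(
        np.int64
    )


def simulate_observations(
    truth: TruthProfile,
    panel: PanelDesign,
    mean_depth: float | None = None,
    seed: int = 0,
    genotypes: np.ndarray | None = None,
    overdispersion: float = 0.0,
) -> pd.DataFrame:
    """Per-SNP tumor/normal allele counts under the purity mixture model.

    Normal depth is Poisson(``mean_depth``); tumor depth is Poisson scaled by
    the expected depth ratio of the SNP's segment; tumor alt counts are
    binomial at the expected BAF with the B allele assigned to a random
    haplotype.  ``overdispersion > 0`` switches depths to gamma-Poisson with
    that squared coefficient of variation.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    if mean_depth is None:
        mean_depth = 300.0
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    gt = draw_genotypes(panel, seed=int(rng.integers(2**31))) if genotypes is None else genotypes
    if len(gt) != len(panel):
        raise ValueError("genotypes length does not match panel size")

    by_chrom: dict[str, list[Segment]] = {}
    for s in truth.segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start)

    p = truth.purity
    psi = truth.ploidy
    nA = np.empty(len(panel), dtype=float)
    nB = np.empty(len(panel), dtype=float)
    for i, snp in enumerate(panel.snps):
        segs = by_chrom.get(snp.chrom)
        if not segs:
            raise ValueError(f"SNP {snp.chrom}:{snp.pos} outside every truth segment")
        starts = [s.start for s in segs]
        j = np.searchsorted(starts, snp.pos, side="right") - 1
        seg = segs[j]
        if not (seg.start <= snp.pos < seg.end):
            raise ValueError(f"SNP {snp.chrom}:{snp.pos} outside every truth segment")
        nA[i], nB[i] = seg.nA, seg.nB

    total = nA + nB
    ratio = expected_depth_ratio(p, psi, total)
    n_depth = _draw_depth(rng, np.full(len(panel), mean_depth), overdispersion)
    t_depth = _draw_depth(rng, mean_depth * ratio, overdispersion)

    n_alt = rng.binomial(n_depth, np.choose(gt, [0.0, 0.5, 1.0]))
    baf = expected_baf(p, nA, nB)
    flip = rng.random(len(panel)) < 0.5
    baf = np.where(flip, 1 - baf, baf)
    t_prob = np.choose(gt, [np.zeros(len(panel)), baf, np.ones(len(panel))])
    t_alt = rng.binomial(t_depth, t_prob)

    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in panel.snps],
            "pos": [s.pos for s in panel.snps],
            "n_ref": n_depth - n_alt,
            "n_alt": n_alt,
            "t_ref": t_depth - t_alt,
            "t_alt": t_alt,
            "normal_gt": gt,
        }
    )


def _draw_depth(rng, mean, overdispersion):
    mean = np.asarray(mean, dtype=float)
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        mean = rng.gamma(shape, mean / shape)
    return rng.poisson(mean)


def _check_same_sites(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if len(a) != len(b) or not (
        (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
        and (a["pos"].to_numpy() == b["pos"].to_numpy()).all()
    ):
        raise ValueError("observation tables cover different site sets")


def mix_purity(
    tumor_obs: pd.DataFrame,
    normal_obs: pd.DataFrame,
    fraction: float,
    seed: int = 0,
) -> pd.DataFrame:
    """In-silico purity dilution: mix tumor and normal reads at f : (1 - f).

    Tumor-side counts of the result are binomial splits of the tumor counts
    (weight ``fraction``) plus splits of the normal aliquot's counts (weight
    ``1 - fraction``); germline columns are carried over unchanged.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    _check_same_sites(tumor_obs, normal_obs)
    out = tumor_obs.copy()
    if fraction == 1.0:
        return out
    rng = np.random.default_rng(seed)
    for col in ("t_ref", "t_alt"):
        t_part = (
            rng.binomial(tumor_obs[col].to_numpy(), fraction)
            if fraction > 0
            else np.zeros(len(tumor_obs), dtype=np.int64)
        )
        n_part = rng.binomial(normal_obs[col].to_numpy(), 1 - fraction)
        out[col] = t_part + n_part
    return out


def downsample_depth(obs: pd.DataFrame, fraction: float, seed: int = 0) -> pd.DataFrame:
    """Binomial read thinning of both samples; fraction 1 is the identity."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return obs.copy()
    rng = np.random.default_rng(seed)
    out = obs.copy()
    for col in ("n_ref", "n_alt", "t_ref", "t_alt"):
        out[col] = rng.binomial(obs[col].to_numpy(), fraction)
    return out
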