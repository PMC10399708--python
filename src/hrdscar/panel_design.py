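"""SNP backbone panel design.

Selects a genome-wide, evenly spaced backbone of common non-exonic SNPs from
a population candidate table.  A candidate survives the site filters iff

* its minor allele frequency exceeds ``min_maf`` in *every* population,
* no exon base lies within ``exon_distance`` bp of the SNP position,
* an exact Hardy-Weinberg equilibrium test is non-significant in every
  population, and
* the probe-window GC fraction (when provided) is within bounds.

The genome is then tiled into ``spacing``-bp windows and, per window, the
single candidate with the highest allele frequency in the designated ranking
population (default the East-Asian / Chinese one) is retained, yielding one
SNP per ~50 kb.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .genome_model import GenomeBuild, GenomicInterval

__all__ = [
    "SNPCandidate",
    "DesignConfig",
    "PanelDesign",
    "FilterResult",
    "hwe_exact_test",
    "apply_site_filters",
    "select_spaced",
    "subset_panel",
    "panel_qc",
]

DEFAULT_POPULATIONS = ("EAS", "EUR", "AFR", "AMR")


@dataclass(frozen=True)
class SNPCandidate:
    """A population SNP considered for the panel.

    ``maf`` maps population key -> minor allele frequency (0..0.5);
    ``genotype_counts`` maps population key -> (hom_ref, het, hom_alt).
    ``gc`` is the probe-window GC fraction, or None if not precomputed.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    maf: dict[str, float]
    genotype_counts: dict[str, tuple[int, int, int]]
    gc: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        for pop, f in self.maf.items():
            if not (0.0 <= f <= 0.5):
                raise ValueError(
                    f"SNP {self.chrom}:{self.pos}: MAF {f} for {pop} outside [0, 0.5]"
                )
        for pop, counts in self.genotype_counts.items():
            if any(c < 0 for c in counts):
                raise ValueError(
                    f"SNP {self.chrom}:{self.pos}: negative genotype count for {pop}"
                )
        if self.gc is not None and not (0.0 <= self.gc <= 1.0):
            raise ValueError(f"SNP {self.chrom}:{self.pos}: GC {self.gc} outside [0, 1]")

    @property
    def label(self) -> str:
        return self.name or f"{self.chrom}:{self.pos + 1}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class DesignConfig:
    """Thresholds of the site filters and spacing selection."""

    min_maf: float = 0.01
    exon_distance: int = 200
    hwe_pvalue: float = 1e-4
    spacing: int = 50_000
    gc_low: float = 0.25
    gc_high: float = 0.75
    populations: tuple[str, ...] = DEFAULT_POPULATIONS
    ranking_population: str = "EAS"

    def __post_init__(self) -> None:
        if self.min_maf <= 0 or self.exon_distance <= 0 or self.spacing <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 <= self.gc_low < self.gc_high <= 1):
            raise ValueError("require 0 <= gc_low < gc_high <= 1")
        if self.ranking_population not in self.populations:
            raise ValueError(
                f"ranking population {self.ranking_population!r} not among "
                f"{self.populations}"
            )


@dataclass
class FilterResult:
    """Outcome of the site filters: survivors plus per-SNP rejection reasons."""

    passed: list[SNPCandidate]
    rejected: list[tuple[SNPCandidate, str]]

    @property
    def reasons(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in self.rejected:
            counts[reason] = counts.get(reason, 0) + 1
        return counts


@dataclass
class PanelDesign:
    """An ordered, spaced set of selected SNPs."""

    snps: list[SNPCandidate]
    spacing: int
    config: DesignConfig = field(default_factory=DesignConfig)
    gap_windows: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(s.chrom, s.pos) for s in self.snps]
        if keys != sorted(keys):
            raise ValueError("panel SNPs must be sorted by (chromosome, position)")
        if len(set(keys)) != len(keys):
            raise ValueError("panel SNP positions must be unique")

    def __len__(self) -> int:
        return len(self.snps)

    def positions(self, chrom: str | None = None) -> list[tuple[str, int]]:
        return [(s.chrom, s.pos) for s in self.snps if chrom is None or s.chrom == chrom]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": s.chrom,
                "start": s.pos,
                "end": s.pos + 1,
                "name": s.label,
                "rank_maf": s.maf.get(self.config.ranking_population, float("nan")),
                "gc": s.gc if s.gc is not None else float("nan"),
            }
            for s in self.snps
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "rank_maf", "gc"]
        )


def hwe_exact_test(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value for one population.

    Full enumeration of heterozygote counts conditional on the observed
    allele counts (the classic exact formulation); the p-value sums the
    probabilities of all heterozygote counts no more probable than the
    observed one.  Returns 1.0 for degenerate (monomorphic or empty) tables.
    """
    n = hom_ref + het + hom_alt
    rare = 2 * min(hom_ref, hom_alt) + het
    if n == 0 or rare == 0:
        return 1.0
    # log-probability of k hets given n genotypes and `rare` rare alleles
    lgamma = math.lgamma

    def log_prob(k: int) -> float:
        hom_r = (rare - k) // 2  # rare homozygotes
        hom_c = n - k - hom_r  # common homozygotes
        return (
            lgamma(n + 1)
            - lgamma(k + 1)
            - lgamma(hom_r + 1)
            - lgamma(hom_c + 1)
            + k * math.log(2)
            + lgamma(rare + 1)
            + lgamma(2 * n - rare + 1)
            - lgamma(2 * n + 1)
        )

    ks = range(rare % 2, rare + 1, 2)
    log_probs = {k: log_prob(k) for k in ks}
    m = max(log_probs.values())
    probs = {k: math.exp(lp - m) for k, lp in log_probs.items()}
    total = sum(probs.values())
    observed = probs[het]
    p = sum(pk for pk in probs.values() if pk <= observed * (1 + 1e-12)) / total
    return min(p, 1.0)


def _exon_distance(chrom: str, pos: int, starts: list[int], ends: list[int]) -> float:
    """Distance in bp from a position to the nearest exon base on its chromosome."""
    if not starts:
        return math.inf
    i = bisect.bisect_right(starts, pos)
    best = math.inf
    if i > 0:
        s, e = starts[i - 1], ends[i - 1]
        best = 0 if pos < e else pos - (e - 1)
    if i < len(starts):
        best = min(best, starts[i] - pos)
    return best


def apply_site_filters(
    candidates: list[SNPCandidate],
    exons: list[GenomicInterval],
    config: DesignConfig | None = None,
) -> FilterResult:
    """Run the MAF / exon-distance / HWE / GC filters over sorted candidates.

    Each rejected SNP carries the first failing rule's label, checked in the
    order ``maf``, ``exon_distance``, ``hwe``, ``gc``.
    """
    config = config or DesignConfig()
    cand_keys = [(c.chrom, c.pos) for c in candidates]
    if cand_keys != sorted(cand_keys):
        raise ValueError("candidates must be sorted by (chromosome, position)")
    exon_keys = [(e.chrom, e.start) for e in exons]
    if exon_keys != sorted(exon_keys):
        raise ValueError("exons must be sorted by (chromosome, start)")

    exon_idx: dict[str, tuple[list[int], list[int]]] = {}
    for e in exons:
        starts, ends = exon_idx.setdefault(e.chrom, ([], []))
        starts.append(e.start)
        ends.append(e.end)

    passed: list[SNPCandidate] = []
    rejected: list[tuple[SNPCandidate, str]] = []
    for cand in candidates:
        reason = _first_failure(cand, exon_idx, config)
        if reason is None:
            passed.append(cand)
        else:
            rejected.append((cand, reason))
    return FilterResult(passed, rejected)


def _first_failure(
    cand: SNPCandidate,
    exon_idx: dict[str, tuple[list[int], list[int]]],
    config: DesignConfig,
) -> str | None:
    for pop in config.populations:
        if pop not in cand.maf:
            raise ValueError(f"SNP {cand.label}: missing allele frequency for {pop}")
    if any(cand.maf[pop] <= config.min_maf for pop in config.populations):
        return "maf"
    starts, ends = exon_idx.get(cand.chrom, ([], []))
    if _exon_distance(cand.chrom, cand.pos, starts, ends) < config.exon_distance:
        return "exon_distance"
    for pop in config.populations:
        counts = cand.genotype_counts.get(pop)
        if counts is None:
            raise ValueError(f"SNP {cand.label}: missing genotype counts for {pop}")
        if hwe_exact_test(*counts) < config.hwe_pvalue:
            return "hwe"
    if cand.gc is not None and not (config.gc_low <= cand.gc <= config.gc_high):
        return "gc"
    return None


def select_spaced(
    passing: list[SNPCandidate],
    genome: GenomeBuild,
    config: DesignConfig | None = None,
) -> PanelDesign:
    """Pick, per spacing window, the candidate with the top ranking-population MAF.

    Ties are broken toward the smaller position for determinism.  Windows
    without any candidate are recorded as coverage gaps.
    """
    config = config or DesignConfig()
    by_window: dict[tuple[str, int], SNPCandidate] = {}
    for cand in passing:
        genome.length_of(cand.chrom)
        key = (cand.chrom, cand.pos // config.spacing)
        best = by_window.get(key)
        if best is None or _rank_key(cand, config) > _rank_key(best, config):
            by_window[key] = cand
    selected = sorted(by_window.values(), key=lambda c: (c.chrom, c.pos))
    gaps = [
        w
        for w in genome.tile_windows(config.spacing)
        if (w.chrom, w.start // config.spacing) not in by_window
    ]
    return PanelDesign(selected, config.spacing, config, gap_windows=gaps)


def _rank_key(cand: SNPCandidate, config: DesignConfig) -> tuple[float, int]:
    return (cand.maf[config.ranking_population], -cand.pos)


def subset_panel(panel: PanelDesign, keep_every: int) -> PanelDesign:
    """Keep every ``keep_every``-th SNP per chromosome, in genomic order."""
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    if keep_every == 1:
        return panel
    kept: list[SNPCandidate] = []
    counter: dict[str, int] = {}
    for snp in panel.snps:
        i = counter.get(snp.chrom, 0)
        if i % keep_every == 0:
            kept.append(snp)
        counter[snp.chrom] = i + 1
    return replace(
        panel, snps=kept, spacing=panel.spacing * keep_every, gap_windows=[]
    )


def panel_qc(panel: PanelDesign, genome: GenomeBuild) -> dict:
    """Summary QC of a panel: counts, densities, spacings, GC, gaps."""
    by_chrom: dict[str, list[int]] = {}
    for snp in panel.snps:
        by_chrom.setdefault(snp.chrom, []).append(snp.pos)
    distances: list[int] = []
    density = {}
    for chrom, positions in by_chrom.items():
        distances.extend(b - a for a, b in zip(positions, positions[1:]))
        density[chrom] = len(positions) / (genome.length_of(chrom) / 1e6)
    gcs = [s.gc for s in panel.snps if s.gc is not None]
    dist_series = pd.Series(distances, dtype=float)
    gc_series = pd.Series(gcs, dtype=float)
    return {
        "n_snps": len(panel.snps),
        "per_chrom_density_per_mb": density,
        "spacing_median": float(dist_series.median()) if distances else float("nan"),
        "spacing_quantiles": (
            dist_series.quantile([0.05, 0.25, 0.5, 0.75, 0.95]).to_dict()
            if distances
            else {}
        ),
        "distances": distances,
        "gc_mean": float(gc_series.mean()) if gcs else float("nan"),
        "gc_quantiles": (
            gc_series.quantile([0.05, 0.5, 0.95]).to_dict() if gcs else {}
        ),
        "n_gap_windows": len(panel.gap_windows),
    }
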