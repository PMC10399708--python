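"""Allele-specific copy number from sparse tumor/normal SNP observations.

The model is the standard purity-ploidy mixture for a bulk tumor sample:
a fraction ``p`` of cells carry the tumor genome and ``1 - p`` a diploid
heterozygous genome.  For a segment with allele-specific copies ``(nA, nB)``
(``nA >= nB``), total ``t = nA + nB``, the expected B-allele fraction at a
germline-heterozygous SNP and the expected tumor/normal depth ratio are::

    BAF(p, nA, nB) = (p * nB + (1 - p)) / (p * t + 2 * (1 - p))
    R(p, psi, t)   = (p * t  + 2 * (1 - p)) / (p * psi + 2 * (1 - p))

with ``psi`` the sample ploidy (length-weighted mean total copy number).
Observed signals are the median-centred ``logR = log2(tumor/normal depth)``
and the folded BAF ``min(VAF, 1 - VAF)`` at normal-het sites.  Purity and
ploidy are fitted by exhaustive grid search of a Gaussian likelihood of
segment means over integer states, and integer ``(nA, nB)`` are assigned
per segment by residual minimisation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome_model import GenomeBuild, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "SiteSignal",
    "Segment",
    "ASCNProfile",
    "PurityPloidyFit",
    "compute_signals",
    "segment_sites",
    "fit_purity_ploidy",
    "assign_ascn",
    "fit_profile",
    "expected_baf",
    "expected_depth_ratio",
    "MAX_TOTAL_CN",
]

MAX_TOTAL_CN = 8
#: integer states (nA, nB) with nA >= nB >= 0 and nA + nB <= MAX_TOTAL_CN
STATES: list[tuple[int, int]] = [
    (a, b)
    for t in range(MAX_TOTAL_CN + 1)
    for b in range(t // 2 + 1)
    for a in [t - b]
    if a >= b
]
_STATE_A = np.array([s[0] for s in STATES])
_STATE_B = np.array([s[1] for s in STATES])
_STATE_T = _STATE_A + _STATE_B

_MIN_RATIO = 0.05  # floor on expected depth ratio (total loss at high purity)
_LOGR_SE_FLOOR = 0.015
_BAF_SE_FLOOR = 0.01


@dataclass(frozen=True)
class SiteSignal:
    """Per-site logR and folded BAF record (BAF is NaN at non-het sites)."""

    chrom: str
    pos: int
    logr: float
    baf: float
    weight: float


@dataclass
class Segment:
    """A genomic segment with signal means and (optionally) assigned copies."""

    chrom: str
    start: int
    end: int
    n_sites: int = 1
    logr: float = math.nan
    baf: float = math.nan
    nA: int | None = None
    nB: int | None = None
    logr_se: float = _LOGR_SE_FLOOR
    baf_se: float = _BAF_SE_FLOOR

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid segment {self.chrom}:{self.start}-{self.end}"
            )
        if self.n_sites < 1:
            raise ValueError("segment must have at least one supporting site")
        if (self.nA is None) != (self.nB is None):
            raise ValueError("nA and nB must be set together")
        if self.nA is not None and not (self.nA >= self.nB >= 0):
            raise ValueError(f"require nA >= nB >= 0, got ({self.nA}, {self.nB})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def state(self) -> tuple[int, int]:
        if self.nA is None:
            raise ValueError("segment has no assigned copy state")
        return (self.nA, self.nB)

    @property
    def has_baf(self) -> bool:
        return not math.isnan(self.baf)


@dataclass
class PurityPloidyFit:
    """Result of the purity/ploidy grid search."""

    purity: float
    ploidy: float
    loglik: float
    surface: pd.DataFrame
    ambiguous: bool


@dataclass
class ASCNProfile:
    """Fitted allele-specific copy-number profile of one tumor sample."""

    purity: float
    ploidy: float
    segments: list[Segment]
    loglik: float = math.nan
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError(f"purity {self.purity} outside (0, 1]")

    def mean_copy_number(self) -> float:
        """Length-weighted mean total copy number of assigned segments."""
        num = sum(s.length * (s.nA + s.nB) for s in self.segments)
        den = sum(s.length for s in self.segments)
        return num / den if den else math.nan


def expected_baf(p: float, nA, nB):
    """Expected folded BAF at a het SNP in state (nA, nB) at purity p."""
    nA = np.asarray(nA, dtype=float)
    nB = np.asarray(nB, dtype=float)
    den = p * (nA + nB) + 2 * (1 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(den > 1e-9, (p * nB + (1 - p)) / np.maximum(den, 1e-9), 0.5)
    return np.minimum(b, 1 - b)


def expected_depth_ratio(p: float, psi: float, total):
    """Expected tumor/normal depth ratio for total copy number `total`."""
    total = np.asarray(total, dtype=float)
    return np.maximum(
        (p * total + 2 * (1 - p)) / (p * psi + 2 * (1 - p)), _MIN_RATIO
    )


# ---------------------------------------------------------------------------
# signals


def compute_signals(obs: pd.DataFrame, min_depth: int = 30) -> pd.DataFrame:
    """Turn raw allele-depth observations into logR / folded-BAF signals.

    Parameters
    ----------
    obs:
        DataFrame with columns chrom, pos, n_ref, n_alt, t_ref, t_alt,
        normal_gt (0 hom-ref / 1 het / 2 hom-alt), sorted by (chrom, pos).
    min_depth:
        Sites below this depth in either sample are dropped.

    Returns a DataFrame with columns chrom, pos, logr, baf, t_alt, t_depth;
    ``baf`` is the folded VAF at normal-het sites and NaN elsewhere;
    ``logr`` is median-centred genome wide.
    """
    keys = list(zip(obs["chrom"], obs["pos"]))
    if keys != sorted(keys):
        raise ValueError("observations must be sorted by (chrom, pos)")
    n_depth = obs["n_ref"].to_numpy() + obs["n_alt"].to_numpy()
    t_depth = obs["t_ref"].to_numpy() + obs["t_alt"].to_numpy()
    n_zero = int((n_depth == 0).sum())
    if n_zero:
        logger.warning("dropping %d sites with zero normal depth", n_zero)
    keep = (n_depth >= max(min_depth, 1)) & (t_depth >= min_depth)
    sub = obs.loc[keep].reset_index(drop=True)
    n_depth = n_depth[keep].astype(float)
    t_depth = t_depth[keep].astype(float)
    logr = np.log2(t_depth / n_depth)
    logr -= np.median(logr)
    vaf = sub["t_alt"].to_numpy() / t_depth
    baf = np.where(sub["normal_gt"].to_numpy() == 1, np.minimum(vaf, 1 - vaf), np.nan)
    return pd.DataFrame(
        {
            "chrom": sub["chrom"],
            "pos": sub["pos"],
            "logr": logr,
            "baf": baf,
            "t_alt": sub["t_alt"],
            "t_depth": t_depth,
        }
    )


# ---------------------------------------------------------------------------
# segmentation


def _noise_sd(values: np.ndarray) -> float:
    """Robust noise sd from median absolute successive differences."""
    v = values[~np.isnan(values)]
    if len(v) < 3:
        return 1.0
    d = np.abs(np.diff(v))
    return max(float(np.median(d)) / (0.6745 * math.sqrt(2)), 1e-3)


def _segment_one_chrom(
    logr: np.ndarray,
    baf: np.ndarray,
    sx: float,
    sy: float,
    penalty: float,
    min_sites: int,
) -> list[int]:
    """Recursive binary segmentation; returns sorted interior breakpoints."""
    n = len(logr)
    cx = np.concatenate([[0.0], np.cumsum(logr)])
    cx2 = np.concatenate([[0.0], np.cumsum(logr**2)])
    b = np.nan_to_num(baf)
    hb = (~np.isnan(baf)).astype(float)
    cy = np.concatenate([[0.0], np.cumsum(b)])
    cy2 = np.concatenate([[0.0], np.cumsum(b**2)])
    cn = np.concatenate([[0.0], np.cumsum(hb)])

    def cost(i: int, j: int) -> float:
        # sum of squared deviations, noise-normalised, over [i, j)
        m = j - i
        sse_x = (cx2[j] - cx2[i]) - (cx[j] - cx[i]) ** 2 / m
        k = cn[j] - cn[i]
        sse_y = 0.0
        if k > 0:
            sse_y = (cy2[j] - cy2[i]) - (cy[j] - cy[i]) ** 2 / k
        return sse_x / sx**2 + sse_y / sy**2

    breaks: list[int] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2 * min_sites:
            continue
        parent = cost(i, j)
        ks = np.arange(i + min_sites, j - min_sites + 1)
        if len(ks) == 0:
            continue
        gains = np.array([parent - cost(i, k) - cost(k, j) for k in ks])
        best = int(np.argmax(gains))
        if gains[best] > penalty:
            k = int(ks[best])
            breaks.append(k)
            stack.append((i, k))
            stack.append((k, j))
    return sorted(breaks)


def segment_sites(
    signals: pd.DataFrame,
    genome: GenomeBuild,
    penalty: float | None = None,
    min_sites: int = 10,
) -> list[Segment]:
    """Piecewise-constant segmentation of the joint (logR, folded BAF) signal.

    Recursive binary segmentation with a penalised gain criterion; breakpoints
    never cross chromosome boundaries.  Segment intervals tile each chromosome
    completely: boundaries fall midway between flanking sites, the first and
    last segments extend to the chromosome ends.
    """
    if penalty is None:
        penalty = 12.0 * math.log(max(len(signals), 2))
    sx = _noise_sd(signals["logr"].to_numpy())
    sy = _noise_sd(signals["baf"].to_numpy())
    segments: list[Segment] = []
    for chrom, grp in signals.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        logr = grp["logr"].to_numpy()
        baf = grp["baf"].to_numpy()
        t_alt = grp["t_alt"].to_numpy(dtype=float)
        t_depth = grp["t_depth"].to_numpy(dtype=float)
        breaks = (
            _segment_one_chrom(logr, baf, sx, sy, penalty, min_sites)
            if len(pos) >= 2
            else []
        )
        bounds = [0, *breaks, len(pos)]
        length = genome.length_of(chrom)
        for a, b in zip(bounds, bounds[1:]):
            start = 0 if a == 0 else (pos[a - 1] + pos[a]) // 2 + 1
            end = length if b == len(pos) else (pos[b - 1] + pos[b]) // 2 + 1
            segments.append(
                _make_segment(chrom, int(start), int(end), logr[a:b], baf[a:b],
                              t_alt[a:b], t_depth[a:b])
            )
    return segments


def _make_segment(
    chrom: str,
    start: int,
    end: int,
    logr: np.ndarray,
    baf: np.ndarray,
    t_alt: np.ndarray,
    t_depth: np.ndarray,
) -> Segment:
    n = len(logr)
    mean_lr = float(np.mean(logr))
    lr_se = max(float(np.std(logr)) / math.sqrt(n), _LOGR_SE_FLOOR)
    het = ~np.isnan(baf)
    if het.sum() >= 3:
        vaf = t_alt[het] / t_depth[het]
        d = t_depth[het]
        # mirror-robust estimate of |BAF - 0.5|: subtract the binomial
        # sampling contribution from the second moment about 0.5
        m2 = float(np.mean((vaf - 0.5) ** 2))
        samp = float(np.mean(t_alt[het] * (d - t_alt[het]) / (d**2 * np.maximum(d - 1, 1))))
        dev = math.sqrt(max(m2 - samp, 0.0))
        mean_baf = 0.5 - dev
        baf_se = max(float(np.std(baf[het])) / math.sqrt(het.sum()), _BAF_SE_FLOOR)
    else:
        mean_baf = math.nan
        baf_se = _BAF_SE_FLOOR
    return Segment(
        chrom, start, end,
        n_sites=n, logr=mean_lr, baf=mean_baf, logr_se=lr_se, baf_se=baf_se,
    )


# ---------------------------------------------------------------------------
# purity / ploidy fit


def _segment_arrays(segments: list[Segment]):
    lr = np.array([s.logr for s in segments])
    lr_se = np.array([s.logr_se for s in segments])
    baf = np.array([s.baf for s in segments])
    baf_se = np.array([s.baf_se for s in segments])
    return lr, lr_se, baf, baf_se


def fit_purity_ploidy(
    segments: list[Segment],
    purity_grid: np.ndarray | None = None,
    ploidy_grid: np.ndarray | None = None,
    tie_tolerance: float = 2.0,
    state_prior_weight: float = 0.1,
) -> PurityPloidyFit:
    """Exhaustive (purity, ploidy) grid search of the segment-mean likelihood.

    For every grid point, each segment is matched to its best integer state
    (nA + nB <= 8) under a Gaussian likelihood of the observed (logR, folded
    BAF) means with their standard errors; the grid point maximising the
    summed log-likelihood wins.  Near-ties (within ``tie_tolerance`` log
    units) that disagree in ploidy or purity raise the ambiguity flag and
    resolve toward the lowest ploidy.

    ``state_prior_weight`` is a weak per-segment log-prior ``-w * |t - 2|``
    on the total copy number ``t`` of the matched state.  The purity-ploidy
    mixture is scale-degenerate (doubling every state and the ploidy leaves
    the model invariant, and the doubled branch has extra intermediate
    states with which to fit noise); the prior breaks that degeneracy toward
    parsimonious near-diploid solutions while remaining negligible against
    any real signal.
    """
    if purity_grid is None:
        purity_grid = np.round(np.arange(0.10, 1.0001, 0.01), 2)
    if ploidy_grid is None:
        ploidy_grid = np.round(np.arange(1.0, 7.0001, 0.1), 1)
    if not any(s.has_baf for s in segments):
        raise ValueError("unidentifiable: no segment has BAF support")
    lr, lr_se, baf, baf_se = _segment_arrays(segments)
    has_baf = ~np.isnan(baf)
    baf_filled = np.nan_to_num(baf)

    # winner selection scans ploidy at 10x the reported grid resolution:
    # the logR offset log2(p*psi + 2(1-p)) changes more slowly in psi at
    # high ploidy, so a coarse grid would systematically favour the
    # ploidy-doubled branch of the degeneracy through quantisation alone
    step = float(ploidy_grid[1] - ploidy_grid[0]) if len(ploidy_grid) > 1 else 0.1
    fine_psi = np.arange(ploidy_grid[0], ploidy_grid[-1] + 1e-9, step / 10)
    coarse_idx = np.searchsorted(fine_psi, ploidy_grid - 1e-9)
    log_floor = math.log2(_MIN_RATIO)
    prior = -state_prior_weight * np.abs(_STATE_T - 2)  # (S,)

    rows = []
    candidates = []  # per-purity refined optimum
    for p in purity_grid:
        ebaf = expected_baf(p, _STATE_A, _STATE_B)  # (S,)
        baf_ll = -0.5 * ((baf_filled[None, :] - ebaf[:, None]) / baf_se) ** 2
        baf_ll = np.where(has_baf[None, :], baf_ll, 0.0) + prior[:, None]  # (S, G)
        log2num = np.log2(np.maximum(p * _STATE_T + 2 * (1 - p), 1e-9))  # (S,)
        offs = np.log2(p * fine_psi + 2 * (1 - p))  # (F,)
        elogr = np.maximum(log2num[None, :] - offs[:, None], log_floor)  # (F, S)
        lr_ll = -0.5 * ((lr[None, None, :] - elogr[:, :, None]) / lr_se) ** 2
        total = (baf_ll[None, :, :] + lr_ll).max(axis=1).sum(axis=1)  # (F,)
        k = int(np.argmax(total))
        candidates.append((float(p), float(fine_psi[k]), float(total[k])))
        for j, psi in zip(coarse_idx, ploidy_grid):
            rows.append((float(p), float(psi), float(total[j])))
    surface = pd.DataFrame(rows, columns=["purity", "ploidy", "loglik"])
    cand = pd.DataFrame(candidates, columns=["purity", "ploidy", "loglik"])
    best_ll = cand["loglik"].max()
    near = cand[cand["loglik"] >= best_ll - tie_tolerance]
    ambiguous = bool(
        near["ploidy"].max() - near["ploidy"].min() > 0.25
        or near["purity"].max() - near["purity"].min() > 0.1
    )
    # resolve toward the lowest ploidy among near-optimal solutions, but only
    # jump branches that are materially lower (> 0.25): within a branch the
    # best-likelihood point wins
    pick = near.sort_values(["loglik", "ploidy"], ascending=[False, True]).iloc[0]
    while True:
        lower = near[near["ploidy"] <= pick["ploidy"] - 0.25]
        if lower.empty:
            break
        pick = lower.sort_values(["loglik", "ploidy"], ascending=[False, True]).iloc[0]
    return PurityPloidyFit(
        purity=float(pick["purity"]),
        ploidy=float(pick["ploidy"]),
        loglik=float(pick["loglik"]),
        surface=surface,
        ambiguous=ambiguous,
    )


def assign_ascn(segments: list[Segment], purity: float, ploidy: float) -> list[Segment]:
    """Assign each segment the integer (nA, nB) minimising model residuals.

    Segments with BAF support minimise the joint squared residual of
    (logR, folded BAF); segments without BAF use logR only and take the
    nearest balanced split of the fitted total copy number.
    """
    ebaf = expected_baf(purity, _STATE_A, _STATE_B)
    elogr = np.log2(expected_depth_ratio(purity, ploidy, _STATE_T))
    totals = np.arange(MAX_TOTAL_CN + 1)
    elogr_total = np.log2(expected_depth_ratio(purity, ploidy, totals))
    out = []
    for seg in segments:
        if seg.has_baf:
            resid = (seg.logr - elogr) ** 2 + (seg.baf - ebaf) ** 2
            a, b = STATES[int(np.argmin(resid))]
        else:
            t = int(np.argmin((seg.logr - elogr_total) ** 2))
            b = t // 2
            a = t - b
        out.append(replace(seg, nA=int(a), nB=int(b)))
    return out


def fit_profile(
    segments: list[Segment],
    purity_grid: np.ndarray | None = None,
    ploidy_grid: np.ndarray | None = None,
) -> ASCNProfile:
    """Grid-fit purity/ploidy, assign integer states, and report the profile.

    The reported ploidy is the length-weighted mean total copy number of the
    assigned states (consistent with its definition), not the grid value.
    """
    fit = fit_purity_ploidy(segments, purity_grid, ploidy_grid)
    assigned = assign_ascn(segments, fit.purity, fit.ploidy)
    profile = ASCNProfile(
        purity=fit.purity,
        ploidy=fit.ploidy,
        segments=assigned,
        loglik=fit.loglik,
        ambiguous=fit.ambiguous,
    )
    mean_cn = profile.mean_copy_number()
    if not math.isnan(mean_cn):
        profile.ploidy = mean_cn
    return profile
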