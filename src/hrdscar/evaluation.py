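"""Desk-scale computational experiments around the HRD pipeline.

Each experiment drives the full chain — simulate observations, derive
logR/BAF signals, segment, fit purity/ploidy, assign integer copies, count
scars — at a series of factor levels (tumor fraction, sequencing depth, or
panel density) and summarises the score series with R-squared and
rank-based AUC statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import simulator
from .ascn import ASCNProfile, compute_signals, fit_profile, segment_sites
from .genome_model import GenomeBuild
from .panel_design import PanelDesign
from .scar_scores import HRD_CUTOFF, ScarConfig, ScarScores, score_hrd
from .simulator import TruthProfile

__all__ = [
    "ExperimentResult",
    "run_pipeline",
    "het_bin_counts",
    "heterozygosity_rate",
    "run_dilution_series",
    "run_depth_series",
    "panel_concordance",
    "auc_rank",
    "r_squared",
]


@dataclass
class ExperimentResult:
    """Per-level pipeline outputs plus summary statistics of one experiment."""

    label: str
    levels: list
    records: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def run_pipeline(
    obs: pd.DataFrame,
    genome: GenomeBuild,
    min_depth: int = 30,
    penalty: float | None = None,
    cutoff: int = HRD_CUTOFF,
    scar_config: ScarConfig | None = None,
) -> tuple[ASCNProfile, ScarScores]:
    """Observations -> signals -> segments -> ASCN fit -> scar scores."""
    signals = compute_signals(obs, min_depth=min_depth)
    segments = segment_sites(signals, genome, penalty=penalty)
    profile = fit_profile(segments)
    scores = score_hrd(profile, genome, cutoff=cutoff, config=scar_config)
    return profile, scores


def r_squared(x, y) -> float:
    """Squared Pearson correlation of two score vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        return 1.0 if np.allclose(x - x.mean(), y - y.mean()) else 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def auc_rank(scores, labels) -> float:
    """Tie-aware rank-sum (Mann-Whitney) AUC of scores against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative labels")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def het_bin_counts(
    obs: pd.DataFrame,
    genome: GenomeBuild,
    bin_size: int = 3_000_000,
    vaf_low: float = 0.3,
    vaf_high: float = 0.7,
    depth_factor: float = 0.2,
    sample: str = "tumor",
) -> pd.DataFrame:
    """Heterozygous-site counts per genomic bin.

    A site counts when its depth exceeds ``depth_factor`` times the sample
    mean depth and its VAF lies in ``[vaf_low, vaf_high]``.  Returns one row
    per bin with columns chrom, start, end, n_het.
    """
    keys = list(zip(obs["chrom"], obs["pos"]))
    if keys != sorted(keys):
        raise ValueError("observations must be sorted by (chrom, pos)")
    ref_col, alt_col = ("t_ref", "t_alt") if sample == "tumor" else ("n_ref", "n_alt")
    depth = obs[ref_col].to_numpy() + obs[alt_col].to_numpy()
    mean_depth = depth.mean() if len(depth) else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, obs[alt_col].to_numpy() / np.maximum(depth, 1), np.nan)
    is_het = (depth > depth_factor * mean_depth) & (vaf >= vaf_low) & (vaf <= vaf_high)
    rows = []
    by_chrom = {c: g for c, g in obs.assign(_het=is_het).groupby("chrom", sort=False)}
    for window in genome.tile_windows(bin_size):
        grp = by_chrom.get(window.chrom)
        if grp is None:
            n = 0
        else:
            pos = grp["pos"].to_numpy()
            sel = (pos >= window.start) & (pos < window.end)
            n = int(grp["_het"].to_numpy()[sel].sum())
        rows.append(
            {"chrom": window.chrom, "start": window.start, "end": window.end, "n_het": n}
        )
    return pd.DataFrame(rows)


def heterozygosity_rate(panel: PanelDesign, genotypes: np.ndarray) -> float:
    """Fraction of called panel genotypes that are heterozygous.

    ``genotypes``: one value per panel SNP; 0/1/2 calls, negative = missing.
    """
    genotypes = np.asarray(genotypes)
    if len(genotypes) != len(panel):
        raise ValueError("genotype vector length does not match panel size")
    called = genotypes >= 0
    if not called.any():
        raise ValueError("all genotypes missing")
    return float((genotypes[called] == 1).sum() / called.sum())


def run_dilution_series(
    truth: TruthProfile,
    panel: PanelDesign,
    genome: GenomeBuild,
    purities: list[float],
    depth: float = 300.0,
    seed: int = 0,
    **pipeline_kw,
) -> ExperimentResult:
    """In-silico tumor-purity dilution: mix tumor with its matched normal.

    The tumor is simulated once at its own purity, a pure-normal aliquot is
    simulated on the same germline genotypes, and each level mixes the two
    at tumor fraction ``f`` before re-running the whole pipeline.
    """
    if any(not (0 < f <= 1) for f in purities):
        raise ValueError("purity fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    gt = simulator.draw_genotypes(panel, seed=int(rng.integers(2**31)))
    tumor_obs = simulator.simulate_observations(
        truth, panel, depth, seed=int(rng.integers(2**31)), genotypes=gt
    )
    normal_truth = simulator.diploid_profile(genome)
    normal_obs = simulator.simulate_observations(
        normal_truth, panel, depth, seed=int(rng.integers(2**31)), genotypes=gt
    )
    result = ExperimentResult("purity_dilution", list(purities))
    for f in purities:
        mixed = simulator.mix_purity(
            tumor_obs, normal_obs, f, seed=int(rng.integers(2**31))
        )
        profile, scores = run_pipeline(mixed, genome, **pipeline_kw)
        result.records.append(
            {
                "purity": f,
                "purity_hat": profile.purity,
                "ploidy_hat": profile.ploidy,
                **scores.as_dict(),
            }
        )
    return result


def run_depth_series(
    truth: TruthProfile,
    panel: PanelDesign,
    genome: GenomeBuild,
    depths: tuple[float, ...] = (50, 100, 150, 200, 250),
    base_depth: float = 300.0,
    seed: int = 0,
    **pipeline_kw,
) -> ExperimentResult:
    """Depth titration: simulate deep, then thin reads to each target depth."""
    if any(d <= 0 for d in depths) or base_depth < max(depths):
        raise ValueError("depths must be positive and <= base_depth")
    rng = np.random.default_rng(seed)
    obs = simulator.simulate_observations(
        truth, panel, base_depth, seed=int(rng.integers(2**31))
    )
    result = ExperimentResult("depth_titration", list(depths))
    for d in depths:
        thinned = simulator.downsample_depth(
            obs, d / base_depth, seed=int(rng.integers(2**31))
        )
        profile, scores = run_pipeline(thinned, genome, **pipeline_kw)
        result.records.append(
            {
                "depth": d,
                "purity_hat": profile.purity,
                "ploidy_hat": profile.ploidy,
                **scores.as_dict(),
            }
        )
    return result


def _restrict(obs: pd.DataFrame, panel: PanelDesign) -> pd.DataFrame:
    sites = set(zip(obs["chrom"], obs["pos"]))
    wanted = panel.positions()
    missing = [s for s in wanted if s not in sites]
    if missing:
        c, p = missing[0]
        raise ValueError(
            f"panel is not a subset of the observed sites "
            f"({len(missing)} missing, first {c}:{p})"
        )
    keep = set(wanted)
    mask = [k in keep for k in zip(obs["chrom"], obs["pos"])]
    return obs.loc[mask].reset_index(drop=True)


def panel_concordance(
    obs_list: list[pd.DataFrame],
    panels: list[PanelDesign],
    genome: GenomeBuild,
    truth_labels: list[int] | None = None,
    cutoff: int = HRD_CUTOFF,
    **pipeline_kw,
) -> ExperimentResult:
    """Score a cohort through each panel; compare score vectors across panels.

    Every panel must be a site subset of each observation table.  The
    summary holds pairwise R-squared between panel score vectors and, when
    truth labels are given, each panel's rank-based AUC against them.
    """
    names = [f"panel_{i}" for i in range(len(panels))]
    scores_by_panel: dict[str, list[int]] = {n: [] for n in names}
    result = ExperimentResult("panel_concordance", names)
    for j, obs in enumerate(obs_list):
        rec: dict = {"sample": j}
        for name, panel in zip(names, panels):
            sub = _restrict(obs, panel)
            profile, scores = run_pipeline(sub, genome, cutoff=cutoff, **pipeline_kw)
            scores_by_panel[name].append(scores.hrd)
            rec[f"{name}_hrd"] = scores.hrd
            rec[f"{name}_purity"] = profile.purity
        result.records.append(rec)
    r2 = {
        f"r2_{a}_vs_{b}": r_squared(scores_by_panel[a], scores_by_panel[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    result.summary.update(r2)
    if truth_labels is not None:
        for name in names:
            result.summary[f"auc_{name}"] = auc_rank(scores_by_panel[name], truth_labels)
    result.summary["scores"] = scores_by_panel
    return result
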