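"""Readers and writers for the on-disk formats.

Conventions: internal coordinates are 0-based half-open everywhere; VCF
input (1-based) is converted on read; panel output is BED with single-base
intervals.  Writers are deterministic: fixed column order and floats at six
significant digits.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ascn import ASCNProfile, Segment
from .genome_model import GenomeBuild, GenomicInterval
from .panel_design import DesignConfig, PanelDesign, SNPCandidate
from .scar_scores import ScarScores
from .simulator import OBS_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "read_observations",
    "write_observations",
    "read_segments",
    "write_segments",
    "read_profile",
    "write_profile",
    "read_candidates",
    "write_candidates",
    "read_bed",
    "write_panel_bed",
    "write_scores",
    "load_design_config",
]

_FLOAT_FMT = "%.6g"


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: _FLOAT_FMT % v if pd.notna(v) else "NA")
    return out


# --- observations -----------------------------------------------------------


def write_observations(obs: pd.DataFrame, path) -> None:
    obs[OBS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing observation columns {sorted(missing)}")
    return df[OBS_COLUMNS]


# --- segments ---------------------------------------------------------------

SEG_COLUMNS = ["chrom", "start", "end", "n_sites", "logr", "baf", "nA", "nB"]


def write_segments(segments: list[Segment], path) -> None:
    rows = []
    for s in segments:
        rows.append(
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_sites": s.n_sites,
                "logr": s.logr,
                "baf": s.baf,
                "nA": s.nA if s.nA is not None else "NA",
                "nB": s.nB if s.nB is not None else "NA",
            }
        )
    df = _format_frame(pd.DataFrame(rows, columns=SEG_COLUMNS))
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based, half-open\n")
        df.to_csv(fh, sep="\t", index=False)


def read_segments(path, genome: GenomeBuild | None = None) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing segment columns {sorted(missing)}")
    segments = []
    for i, row in enumerate(df.itertuples(), start=2):
        if genome is not None:
            genome.length_of(str(row.chrom))  # raises on unknown chromosome
        has_cn = pd.notna(row.nA) and pd.notna(row.nB)
        segments.append(
            Segment(
                str(row.chrom),
                int(row.start),
                int(row.end),
                n_sites=int(row.n_sites),
                logr=float(row.logr) if pd.notna(row.logr) else float("nan"),
                baf=float(row.baf) if pd.notna(row.baf) else float("nan"),
                nA=int(row.nA) if has_cn else None,
                nB=int(row.nB) if has_cn else None,
            )
        )
    by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"{path}: overlapping segments on {chrom} at {b.start}"
                )
    return segments


def write_profile(profile: ASCNProfile, seg_path, json_path) -> None:
    write_segments(profile.segments, seg_path)
    meta = {
        "purity": round(profile.purity, 6),
        "ploidy": round(profile.ploidy, 6),
        "loglik": round(profile.loglik, 6),
        "ambiguous": profile.ambiguous,
    }
    Path(json_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_profile(seg_path, json_path, genome: GenomeBuild | None = None) -> ASCNProfile:
    meta = json.loads(Path(json_path).read_text())
    return ASCNProfile(
        purity=meta["purity"],
        ploidy=meta["ploidy"],
        segments=read_segments(seg_path, genome),
        loglik=meta.get("loglik", float("nan")),
        ambiguous=meta.get("ambiguous", False),
    )


# --- candidates -------------------------------------------------------------


def _candidate_tsv_columns(populations) -> list[str]:
    cols = ["chrom", "pos", "ref", "alt", "gc"]
    for pop in populations:
        cols += [f"{pop}_maf", f"{pop}_homref", f"{pop}_het", f"{pop}_homalt"]
    return cols


def write_candidates(candidates: list[SNPCandidate], path, populations=None) -> None:
    if populations is None:
        populations = sorted(candidates[0].maf) if candidates else []
    rows = []
    for c in candidates:
        row = {
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "gc": c.gc if c.gc is not None else float("nan"),
        }
        for pop in populations:
            row[f"{pop}_maf"] = c.maf[pop]
            row[f"{pop}_homref"], row[f"{pop}_het"], row[f"{pop}_homalt"] = (
                c.genotype_counts[pop]
            )
        rows.append(row)
    df = _format_frame(pd.DataFrame(rows, columns=_candidate_tsv_columns(populations)))
    df.to_csv(path, sep="\t", index=False)


def _read_candidates_tsv(path, populations) -> list[SNPCandidate]:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    out = []
    for i, row in enumerate(df.itertuples(), start=2):
        maf, counts = {}, {}
        for pop in populations:
            key = f"{pop}_maf"
            if key not in df.columns:
                raise ValueError(f"{path}: missing column {key}")
            maf[pop] = float(getattr(row, key))
            counts[pop] = (
                int(getattr(row, f"{pop}_homref")),
                int(getattr(row, f"{pop}_het")),
                int(getattr(row, f"{pop}_homalt")),
            )
        gc = getattr(row, "gc", float("nan"))
        out.append(
            SNPCandidate(
                str(row.chrom),
                int(row.pos),
                str(row.ref),
                str(row.alt),
                maf=maf,
                genotype_counts=counts,
                gc=float(gc) if pd.notna(gc) else None,
            )
        )
    return out


def _read_candidates_vcf(path, populations) -> list[SNPCandidate]:
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        maf, counts = {}, {}
        for pop in populations:
            af = rec.INFO.get(f"{pop}_AF")
            gc3 = rec.INFO.get(f"{pop}_GC")
            if af is None or gc3 is None:
                raise ValueError(
                    f"{path}: record {rec.CHROM}:{rec.POS} missing INFO "
                    f"{pop}_AF or {pop}_GC"
                )
            af = float(af)
            maf[pop] = min(af, 1 - af)
            parts = [int(x) for x in str(gc3).split(",")]
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: record {rec.CHROM}:{rec.POS}: {pop}_GC must be "
                    "hom_ref,het,hom_alt"
                )
            counts[pop] = tuple(parts)
        gc = rec.INFO.get("PROBE_GC")
        out.append(
            SNPCandidate(
                rec.CHROM,
                rec.POS - 1,  # VCF is 1-based
                rec.REF,
                rec.ALT[0] if rec.ALT else "N",
                maf=maf,
                genotype_counts=counts,
                gc=float(gc) if gc is not None else None,
                name=rec.ID,
            )
        )
    return out


def read_candidates(path, populations=None) -> list[SNPCandidate]:
    """Read SNP candidates from a VCF (with per-population INFO fields) or TSV."""
    populations = tuple(populations) if populations else DesignConfig().populations
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_candidates_vcf(path, populations)
    return _read_candidates_tsv(path, populations)


# --- BED / panel ------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            intervals.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start))


def write_panel_bed(panel: PanelDesign, path) -> None:
    df = panel.to_frame()
    df["rank_maf"] = df["rank_maf"].map(lambda v: _FLOAT_FMT % v)
    df[["chrom", "start", "end", "name", "rank_maf"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_scores(scores: ScarScores, path) -> None:
    Path(path).write_text(json.dumps(scores.as_dict(), indent=2) + "\n")


# --- config -----------------------------------------------------------------

_DESIGN_KEYS = {
    "schema_version",
    "min_maf",
    "exon_distance",
    "hwe_pvalue",
    "spacing",
    "gc_low",
    "gc_high",
    "populations",
    "ranking_population",
}


def load_design_config(path) -> DesignConfig:
    """Load a design YAML; unknown keys warn, never silently ignored."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _DESIGN_KEYS
    if unknown:
        warnings.warn(f"{path}: ignoring unknown config keys {sorted(unknown)}")
    kwargs = {k: v for k, v in raw.items() if k in _DESIGN_KEYS - {"schema_version"}}
    if "populations" in kwargs:
        kwargs["populations"] = tuple(kwargs["populations"])
    return DesignConfig(**kwargs)
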