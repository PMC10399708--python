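"""Independent brute-force reference implementations used only by tests.

These re-derive the scar-count definitions, the exact Hardy-Weinberg test
and the panel-selection rules with naive enumeration, deliberately avoiding
the package's own data structures and algorithms.
"""

from __future__ import annotations

from math import comb

MB = 1_000_000
_SEX = {"chrX", "chrY", "X", "Y"}


def oracle_scar_counts(rows, genome, include_sex=False):
    """Count (LOH, TAI, LST) on smoothed segment tuples (chrom, start, end, nA, nB).

    Breakpoint-centric LST formulation: a break counts when it lies strictly
    inside an arm and the flanking states differ with >= 11 Mb of each flank
    inside that arm.
    """
    loh = tai = lst = 0
    chroms = sorted({r[0] for r in rows})
    for chrom in chroms:
        if chrom in _SEX and not include_sex:
            continue
        segs = sorted((r for r in rows if r[0] == chrom), key=lambda r: r[1])
        cov0 = segs[0][1]
        cov1 = max(r[2] for r in segs)
        cen = genome.centromere(chrom)

        # --- LOH: nB = 0, nA >= 1, > 15 Mb, not the whole covered extent
        for _, s, e, a, b in segs:
            if b == 0 and a >= 1 and e - s > 15 * MB and not (s == cov0 and e == cov1):
                loh += 1

        # --- TAI: maximal imbalanced runs touching a covered end,
        # not overlapping the centromere
        i = 0
        while i < len(segs):
            _, s, e, a, b = segs[i]
            if a == b:
                i += 1
                continue
            run_start, run_end = s, e
            j = i + 1
            while (
                j < len(segs)
                and segs[j][1] == run_end
                and segs[j][3] != segs[j][4]
            ):
                run_end = segs[j][2]
                j += 1
            touches = run_start == cov0 or run_end == cov1
            overlaps_cen = run_start < cen.end and run_end > cen.start
            if touches and not overlaps_cen:
                tai += 1
            i = j

        # --- LST: breakpoint-centric, per arm
        length = genome.length_of(chrom)
        for arm_start, arm_end in ((0, cen.start), (cen.end, length)):
            for (c1, s1, e1, a1, b1), (c2, s2, e2, a2, b2) in zip(segs, segs[1:]):
                bp = e1
                if bp != s2 or (a1, b1) == (a2, b2):
                    continue
                if not (arm_start < bp < arm_end):
                    continue
                left = bp - max(s1, arm_start)
                right = min(e2, arm_end) - bp
                if left >= 11 * MB and right >= 11 * MB:
                    lst += 1
    return loh, tai, lst


def oracle_hwe_exact(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact HWE p-value by integer enumeration of heterozygote counts."""
    n = hom_ref + het + hom_alt
    rare = 2 * min(hom_ref, hom_alt) + het
    if n == 0 or rare == 0:
        return 1.0

    def weight(k: int) -> int:
        hom_r = (rare - k) // 2
        return comb(n, k) * comb(n - k, hom_r) * 2**k

    weights = {k: weight(k) for k in range(rare % 2, rare + 1, 2)}
    total = sum(weights.values())
    observed = weights[het]
    return sum(w for w in weights.values() if w <= observed) / total


def oracle_panel(candidates, exons, genome, config):
    """Naive re-implementation of the five selection rules (a)-(e)."""
    survivors = []
    for c in candidates:
        if any(c.maf[p] <= config.min_maf for p in config.populations):
            continue
        dists = [
            0
            if e.start <= c.pos < e.end
            else min(abs(c.pos - e.start), abs(c.pos - (e.end - 1)))
            for e in exons
            if e.chrom == c.chrom
        ]
        if dists and min(dists) < config.exon_distance:
            continue
        if any(
            oracle_hwe_exact(*c.genotype_counts[p]) < config.hwe_pvalue
            for p in config.populations
        ):
            continue
        if c.gc is not None and not (config.gc_low <= c.gc <= config.gc_high):
            continue
        survivors.append(c)
    panel = []
    for w in genome.tile_windows(config.spacing):
        in_window = [
            c for c in survivors if c.chrom == w.chrom and w.start <= c.pos < w.end
        ]
        if in_window:
            panel.append(
                max(
                    in_window,
                    key=lambda c: (c.maf[config.ranking_population], -c.pos),
                )
            )
    return survivors, sorted(panel, key=lambda c: (c.chrom, c.pos))
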