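"""Site filters, HWE exact test, spaced selection, subsetting and QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrdscar.genome_model import GenomeBuild, GenomicInterval
from hrdscar.panel_design import (
    DesignConfig,
    PanelDesign,
    SNPCandidate,
    apply_site_filters,
    hwe_exact_test,
    panel_qc,
    select_spaced,
    subset_panel,
)
from hrdscar.simulator import synthetic_panel

from .oracles import oracle_hwe_exact, oracle_panel

POPS = DesignConfig().populations


def make_candidate(chrom="chr1", pos=1_000_000, maf=0.3, gc=0.45,
                   counts=(250, 430, 180), **overrides):
    mafs = {p: maf for p in POPS}
    mafs.update(overrides.pop("mafs", {}))
    gcounts = {p: counts for p in POPS}
    gcounts.update(overrides.pop("gcounts", {}))
    return SNPCandidate(chrom, pos, "A", "G", maf=mafs, genotype_counts=gcounts,
                        gc=gc, **overrides)


class TestHWEExactTest:
    @pytest.mark.parametrize(
        "counts",
        [(90, 0, 10), (25, 50, 25), (1, 1, 1), (0, 5, 0), (40, 20, 40),
         (100, 0, 0), (3, 14, 83), (0, 0, 0), (7, 1, 0)],
    )
    def test_matches_integer_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            oracle_hwe_exact(*counts), rel=1e-9
        )

    def test_extreme_het_deficit_is_highly_significant(self):
        # 90/0/10 of n=100: no hets despite 10% rare-allele frequency
        assert hwe_exact_test(90, 0, 10) < 1e-10

    def test_equilibrium_counts_are_not_significant(self):
        assert hwe_exact_test(250, 430, 180) > 0.01

    @given(
        hom_ref=st.integers(0, 60),
        het=st.integers(0, 60),
        hom_alt=st.integers(0, 60),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_is_a_valid_pvalue_and_matches_oracle(self, hom_ref, het, hom_alt):
        p = hwe_exact_test(hom_ref, het, hom_alt)
        assert 0 <= p <= 1
        assert p == pytest.approx(oracle_hwe_exact(hom_ref, het, hom_alt), rel=1e-9)


class TestSiteFilters:
    def test_clean_candidate_is_retained(self):
        cand = make_candidate(mafs={"EAS": 0.25, "EUR": 0.30, "AFR": 0.20, "AMR": 0.22})
        exons = [GenomicInterval("chr1", 1_000_500, 1_000_700)]  # 500 bp away
        result = apply_site_filters([cand], exons, DesignConfig())
        assert result.passed == [cand] and not result.rejected

    def test_low_maf_in_one_population_rejects_with_reason(self):
        cand = make_candidate(mafs={"AFR": 0.005})
        result = apply_site_filters([cand], [], DesignConfig())
        assert result.rejected == [(cand, "maf")]

    def test_maf_threshold_is_strict(self):
        at_threshold = make_candidate(mafs={"EUR": 0.01})
        above = make_candidate(pos=2_000_000, mafs={"EUR": 0.0101})
        result = apply_site_filters([at_threshold, above], [], DesignConfig())
        assert result.passed == [above]
        assert result.rejected[0][1] == "maf"

    @pytest.mark.parametrize("offset, kept", [(150, False), (200, True), (500, True)])
    def test_exon_distance_boundary(self, offset, kept):
        # exclusion: distance to the nearest exon base must be >= 200 bp
        cand = make_candidate(pos=1_000_000)
        exons = [GenomicInterval("chr1", 1_000_000 + offset, 1_000_000 + offset + 100)]
        result = apply_site_filters([cand], exons, DesignConfig())
        assert (result.passed == [cand]) is kept
        if not kept:
            assert result.rejected[0][1] == "exon_distance"

    def test_hwe_deviant_population_rejects(self):
        cand = make_candidate(gcounts={"EAS": (90, 0, 10)})
        result = apply_site_filters([cand], [], DesignConfig())
        assert result.rejected[0][1] == "hwe"

    def test_gc_outside_bounds_rejects(self):
        cand = make_candidate(gc=0.80)
        result = apply_site_filters([cand], [], DesignConfig())
        assert result.rejected[0][1] == "gc"

    def test_missing_population_frequency_names_the_snp(self):
        cand = SNPCandidate(
            "chr1", 5, "A", "G",
            maf={"EAS": 0.3}, genotype_counts={p: (10, 10, 10) for p in POPS},
        )
        with pytest.raises(ValueError, match="chr1:6"):
            apply_site_filters([cand], [], DesignConfig())

    def test_unsorted_input_rejected(self):
        cands = [make_candidate(pos=2_000_000), make_candidate(pos=1_000_000)]
        with pytest.raises(ValueError, match="sorted"):
            apply_site_filters(cands, [], DesignConfig())

    def test_filtering_is_order_independent_over_permutations(self):
        rng = np.random.default_rng(0)
        cands = sorted(
            (make_candidate(pos=int(p), maf=float(m), gc=float(g))
             for p, m, g in zip(
                 rng.choice(10_000_000, 30, replace=False),
                 rng.uniform(0.005, 0.5, 30),
                 rng.uniform(0.1, 0.9, 30),
             )),
            key=lambda c: c.pos,
        )
        exons = [GenomicInterval("chr1", 3_000_000, 3_001_000)]
        baseline = {c.pos for c in apply_site_filters(cands, exons).passed}
        for _ in range(5):
            rng.shuffle(cands)
            resorted = sorted(cands, key=lambda c: (c.chrom, c.pos))
            assert {c.pos for c in apply_site_filters(resorted, exons).passed} == baseline

    def test_tightening_thresholds_never_increases_survivors(self):
        rng = np.random.default_rng(1)
        cands = sorted(
            (make_candidate(pos=int(p), maf=float(m))
             for p, m in zip(rng.choice(10_000_000, 40, replace=False),
                             rng.uniform(0.005, 0.5, 40))),
            key=lambda c: c.pos,
        )
        exons = [GenomicInterval("chr1", 2_000_000, 2_000_500)]
        loose = len(apply_site_filters(cands, exons, DesignConfig()).passed)
        for tighter in (
            DesignConfig(min_maf=0.1),
            DesignConfig(exon_distance=2_000_000),
            DesignConfig(hwe_pvalue=0.99),
        ):
            assert len(apply_site_filters(cands, exons, tighter).passed) <= loose


class TestSelectSpaced:
    def test_highest_ranking_population_maf_wins_window(self, simple_genome):
        cands = [
            make_candidate(pos=10_000, mafs={"EAS": 0.1}),
            make_candidate(pos=20_000, mafs={"EAS": 0.4}),
            make_candidate(pos=30_000, mafs={"EAS": 0.3}),
        ]
        panel = select_spaced(cands, simple_genome, DesignConfig())
        assert [s.pos for s in panel.snps[:1]] == [20_000]

    def test_ties_break_toward_smaller_position(self, simple_genome):
        cands = [
            make_candidate(pos=10_000, mafs={"EAS": 0.4}),
            make_candidate(pos=20_000, mafs={"EAS": 0.4}),
        ]
        panel = select_spaced(cands, simple_genome, DesignConfig())
        assert panel.snps[0].pos == 10_000

    def test_empty_windows_are_recorded_as_gaps(self, simple_genome):
        cands = [make_candidate(pos=10_000)]
        panel = select_spaced(cands, simple_genome, DesignConfig())
        n_windows = len(simple_genome.tile_windows(50_000))
        assert len(panel.gap_windows) == n_windows - 1

    def test_empty_input_gives_empty_panel_all_gaps(self, simple_genome):
        panel = select_spaced([], simple_genome, DesignConfig())
        assert len(panel) == 0
        assert len(panel.gap_windows) == len(simple_genome.tile_windows(50_000))

    def test_one_candidate_per_window_spacing(self, simple_genome):
        cands = [make_candidate(pos=p) for p in (10_000, 60_000, 110_000)]
        panel = select_spaced(cands, simple_genome, DesignConfig())
        gaps = np.diff([s.pos for s in panel.snps])
        assert len(panel) == 3 and all(g == 50_000 for g in gaps)

    def test_at_most_one_snp_per_window(self, simple_genome):
        rng = np.random.default_rng(3)
        cands = sorted(
            (make_candidate(pos=int(p), maf=float(rng.uniform(0.05, 0.5)))
             for p in rng.choice(5_000_000, 200, replace=False)),
            key=lambda c: c.pos,
        )
        panel = select_spaced(cands, simple_genome, DesignConfig())
        windows = {s.pos // 50_000 for s in panel.snps}
        assert len(windows) == len(panel)


class TestSubsetPanel:
    def test_keep_every_one_is_identity(self, toy_panel):
        assert subset_panel(toy_panel, 1) is toy_panel

    def test_half_density_doubles_median_spacing(self, toy_panel):
        half = subset_panel(toy_panel, 2)
        chroms = {s.chrom for s in toy_panel.snps}
        expected = sum(
            -(-len([s for s in toy_panel.snps if s.chrom == c]) // 2) for c in chroms
        )
        assert len(half) == expected
        full_med = np.median(np.diff([s.pos for s in toy_panel.snps if s.chrom == "chr1"]))
        half_med = np.median(np.diff([s.pos for s in half.snps if s.chrom == "chr1"]))
        assert half_med == pytest.approx(2 * full_med, rel=0.2)

    def test_ceiling_count_per_chromosome(self):
        # 52592-SNP scale panel subset 6x keeps ceil(n_c / 6) per chromosome
        genome = GenomeBuild(
            [("chr1", 1_500_000_000), ("chr2", 1_129_600_000)],
            {"chr1": (700_000_000, 703_000_000), "chr2": (500_000_000, 503_000_000)},
        )
        panel = synthetic_panel(genome, spacing=50_000, seed=0)
        assert len(panel) == 52_592
        sub = subset_panel(panel, 6)
        expected = sum(
            -(-len([s for s in panel.snps if s.chrom == c]) // 6)
            for c in ("chr1", "chr2")
        )
        assert len(sub) == expected == 8766

    def test_keep_every_below_one_rejected(self, toy_panel):
        with pytest.raises(ValueError):
            subset_panel(toy_panel, 0)


class TestPanelQC:
    def test_three_snp_distances(self, simple_genome):
        snps = [make_candidate(pos=p) for p in (0, 50_000, 100_000)]
        panel = PanelDesign(snps, 50_000)
        qc = panel_qc(panel, simple_genome)
        assert qc["distances"] == [50_000, 50_000]
        assert qc["n_snps"] == 3

    def test_empty_panel(self, simple_genome):
        qc = panel_qc(PanelDesign([], 50_000), simple_genome)
        assert qc["n_snps"] == 0 and qc["distances"] == []

    def test_spacing_concentrates_near_target(self, toy, toy_panel):
        # one SNP per gap-free 50-kb window bounds every distance by 2x the
        # spacing; with uniform placement inside windows the distance is
        # triangular on (0, 100 kb), so 87.5% falls within [0.5x, 2x]
        qc = panel_qc(toy_panel, toy)
        d = np.array(qc["distances"])
        assert d.max() <= 100_000
        assert np.mean((d >= 25_000) & (d <= 100_000)) >= 0.85
        assert qc["spacing_median"] == pytest.approx(50_000, rel=0.1)


class TestBruteForceOracle:
    def test_full_design_matches_naive_enumeration(self, simple_genome):
        rng = np.random.default_rng(7)
        n = 400
        positions = np.sort(rng.choice(20_000_000, n, replace=False))
        cands = []
        for pos in positions:
            mafs = {p: float(rng.uniform(0.003, 0.5)) for p in POPS}
            counts = {}
            for p in POPS:
                if rng.random() < 0.05:  # occasional strong HWE violation
                    counts[p] = (90, 0, 10)
                else:
                    f = mafs[p]
                    het = int(2 * f * (1 - f) * 500)
                    ha = int(f * f * 500)
                    counts[p] = (500 - het - ha, het, ha)
            gc = float(rng.uniform(0.1, 0.9)) if rng.random() < 0.9 else None
            cands.append(
                SNPCandidate("chr1", int(pos), "A", "G", maf=mafs,
                             genotype_counts=counts, gc=gc)
            )
        exons = [
            GenomicInterval("chr1", int(s), int(s) + 400)
            for s in np.sort(rng.choice(20_000_000, 50, replace=False))
        ]
        exons.sort(key=lambda e: e.start)
        config = DesignConfig()
        result = apply_site_filters(cands, exons, config)
        panel = select_spaced(result.passed, simple_genome, config)
        oracle_passed, oracle_sel = oracle_panel(cands, exons, simple_genome, config)
        assert [c.pos for c in result.passed] == [c.pos for c in oracle_passed]
        assert [c.pos for c in panel.snps] == [c.pos for c in oracle_sel]
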