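# Methods

## The measurement problem

A bulk tumor sample is a mixture: a fraction *p* (purity) of tumor cells
whose genome is piecewise-constant in allele-specific copy number, and
1 − *p* normal diploid cells. At a germline-heterozygous SNP inside a
segment with allele copies (nA, nB), nA ≥ nB, total t = nA + nB, the
expected B-allele fraction and tumor/normal depth ratio are

    BAF(p, nA, nB) = (p·nB + (1 − p)) / (p·t + 2(1 − p))
    R(p, ψ, t)     = (p·t + 2(1 − p)) / (p·ψ + 2(1 − p))

with ψ the sample ploidy, defined throughout as the length-weighted mean
total copy number. The observed signals are logR = log2(tumor/normal
depth), median-centred genome-wide, and the folded BAF min(V, 1 − V) at
sites called heterozygous in the matched normal. From segments of these
signals the package infers (p, ψ, {nA, nB}) and counts the three genomic
scars.

## Scar definitions and conventions

Counting operates on a smoothed profile: touching segments with equal
(nA, nB) are merged, then the shortest segment under 3 Mb is repeatedly
removed — equal flanks fuse across it, unequal flanks each extend to its
midpoint — until no sub-3-Mb segment remains. The procedure is idempotent
and order-deterministic (shortest first, ties to the left).

* **HRD-LOH**: segments with nB = 0 and nA ≥ 1, strictly longer than
  15 Mb, not spanning the whole covered extent of their chromosome.
  Homozygous deletions (0, 0) are not LOH: no allele remains to lose
  heterozygosity toward, and in practice such segments are short.
* **HRD-TAI**: maximal runs of touching segments with nA ≠ nB that reach
  the first or last covered base of the chromosome and whose interval does
  not overlap the centromere. No minimum run size beyond the 3-Mb
  smoothing is applied by default; `ScarConfig.min_tai_size` exposes one,
  since published implementations differ on this point.
* **HRD-LST**: segments are clipped to the p and q arms (the centromere
  interval is excised); within an arm, a breakpoint between touching parts
  with different states counts when **both** parts are ≥ 11 Mb.
  Breakpoints falling inside the centromere disappear with the clipping,
  which realises "breaks at the centromere are not counted". The
  both-flanks reading of "adjacent regions of at least 11 Mb" is the
  standard one; `ScarConfig.lst_min_segment` exposes the threshold.
* **HRD score** = LOH + TAI + LST; positive when ≥ cutoff (default 42,
  inclusive — the threshold convention is exposed because only the cutoff
  value, not its inclusivity, is standardised).
* Sex chromosomes are excluded from all counts by default
  (`ScarConfig.include_sex`): a single X in males makes the autosome
  conventions meaningless there.

Centromere coordinates are an input, not an assumption: the packaged
GRCh37 table uses the UCSC hg19 centromere gap intervals, and any
chrom/length/cen_start/cen_end TSV can replace it.

## ASCN inference

**Signals.** Sites below 30 reads in either sample are dropped (depth
floor for a usable allele fraction at panel depths of 200–300×). logR is
median-centred; folded BAF is computed at normal-het sites only.

**Segmentation** is recursive binary splitting on the joint signal, cost =
SSE(logR)/σ²_R + SSE(BAF)/σ²_B with noise scales estimated from median
absolute successive differences; a split is accepted when the cost drop
exceeds a penalty (default 12·log n) and both sides keep ≥ 10 sites.
Segment boundaries fall midway between flanking SNPs and extend to the
chromosome ends, so segment lengths are genomic lengths — the scar rules
need real megabases, not site counts.

**Segment BAF estimator.** The naive mean of folded per-site VAFs is
biased downward near 0.5 (folding noise), which would masquerade as
allelic imbalance in balanced segments. Instead the segment-level
deviation is estimated as √max(0, m₂ − v̂), where m₂ is the mean squared
deviation of VAF from 0.5 and v̂ the unbiased binomial sampling
contribution alt·(d − alt)/(d²(d − 1)) averaged over sites; the folded
mean is 0.5 minus that deviation. This is mirror-robust (allele
orientation is irrelevant) and removes most of the folding bias.

**Purity–ploidy fit.** Exhaustive grid search, purity 0.10–1.00 step 0.01
and ploidy 1.0–7.0 step 0.1, of a Gaussian log-likelihood of segment means
(standard errors floored at 0.015 logR / 0.01 BAF units) with each segment
matched to its best integer state, nA + nB ≤ 8. Two deliberate additions:

* *Fine ploidy selection.* The likelihood depends on ψ only through the
  offset log2(p·ψ + 2(1 − p)), whose grid spacing is about twice as fine
  at ψ = 4 as at ψ = 2; on the coarse grid alone the ploidy-doubled
  solution wins by quantisation. The reported surface stays on the
  documented grid, but the winner is chosen on a 10×-finer ploidy scan.
* *State-complexity prior.* The mixture is scale-degenerate: doubling all
  states and ψ reproduces the data exactly, and the doubled branch has
  extra intermediate states with which to fit noise, so it can win by
  several log units. A weak per-segment prior −0.1·|t − 2| breaks the
  degeneracy toward parsimonious near-diploid solutions; against any real
  signal (tens to hundreds of log units per segment) it is negligible.

Near-optimal solutions within 2 log units that disagree in ploidy by
> 0.25 or purity by > 0.1 set the `ambiguous` flag; among near-ties the
materially lowest-ploidy branch is returned (within a branch, the best
likelihood). A genome that is entirely (1, 1) is flagged: BAF is 0.5 and
logR is 0 for every purity, so (p, ψ = 2) is a ridge. A fit with no
BAF-supporting segment raises an error rather than guessing.

**Assignment.** Each segment takes the integer (nA, nB) minimising the
squared (logR, BAF) residual at the fitted (p, ψ); segments without BAF
support use logR only and split the total as evenly as possible. The
reported ploidy is recomputed as the length-weighted mean total copy
number of the assignment, which is the quantity's definition; the grid ψ
is an internal nuisance parameter.

## The synthetic-tumor generator

The generator's purpose is a ground truth whose scar counts are known *by
construction*, so that the scorer can be validated against the plan rather
than against itself. Geometry, on a diploid (1, 1) background:

* **LOH event** — one arm: a (1, 0) segment from a 3.5–10.5 Mb telomeric
  remainder to the centromere boundary (so ≥ 16 Mb, interstitial, and its
  single internal breakpoint has a sub-11 Mb flank → no LST side-effect).
* **TAI event** — one arm: a (2, 1) segment from the telomere leaving a
  3.5–10.5 Mb balanced remainder before the centromere (reaches the
  sub-telomere, never overlaps the centromere, no countable break).
* **LST events** — an arm tiled with alternating (1, 1)/(2, 2) blocks, all
  ≥ 12 Mb; k + 1 blocks plant exactly k transitions. Blocks are sized
  12 Mb + Dirichlet-distributed slack. The 12 Mb default (vs the 11 Mb
  rule) leaves margin for breakpoint placement error of ± half the SNP
  spacing, as physical reference standards carry unambiguous events.
* **Decoys** — sub-3 Mb aberrant blips with ≥ 3.5 Mb margins inside
  otherwise diploid arms; the smoothing pass must erase them.

Remainders below 11 Mb and centromere-anchored placement make every event
score exactly once and nothing else score at all, so the planted ledger
(n_loh, n_tai, n_lst) *is* the expected score triple — verified
exhaustively in the round-trip tests. Sex chromosomes are never planted.
Each LOH/TAI event occupies one arm, so per-class counts are bounded by
arm count and arm length; infeasible specifications raise an error naming
the event.

Observations: normal genotypes are Hardy–Weinberg draws from each SNP's
ranking-population allele frequency; depths are Poisson (optionally
gamma-Poisson via an overdispersion parameter); tumor alt counts are
binomial at the mixture BAF with the B allele assigned to a random
haplotype (scoring uses folded BAF, so orientation never matters). Purity
dilution mixes tumor and matched-normal read counts binomially at
f : 1 − f (count-level mixing; the read- vs count-level distinction is
immaterial for count statistics). Depth titration is binomial thinning of
both samples, which preserves allele fractions in expectation.

## Study conditions and problem sizes

The in-silico experiments emulate reference-standard conditions: 300×
mean depth, purity 1.0 diluted to {0.1, 0.3, 0.5, 0.8}, depth subsets
{50, 100, 150, 200, 250}×, and two reference tumors — scar-rich
(12/12/26 events, HRD 50) and near-diploid (1/1/1, HRD 3). Panels for
GRCh37-scale experiments use 100 kb spacing (~29 k SNPs, half the density
of a production 50 kb panel) and cohorts of 30 tumors; purity/ploidy
recovery uses a 3×100 Mb toy genome at 50 kb spacing with 20 tumors per
condition cell. These sizes were chosen so the whole validation runs on a
single CPU in minutes; the concordance cohort is drawn as a low-scar and
a high-scar group (clearly either side of cutoff 42), mirroring low/high
reference standards — integer scar counts fluctuate by ±1–2 under
resampling, so a cohort dense near the cutoff could not exhibit perfect
truth-label separation on principle.

## What the generator does not emulate

Synthetic data here have no GC-content or mappability bias in depth, no
FFPE artifacts, no subclonal (fractional) copy states, no germline CNVs,
and SNP capture is uniform. Passing tests therefore demonstrate the
correctness of the scoring and inference chain under the stated mixture
model, not robustness to platform-specific noise; on real capture data an
upstream GC correction would be advisable before trusting logR.

## Panel design details

The Hardy–Weinberg test is the exact conditional test (full enumeration of
heterozygote counts given allele counts), with "significant deviation" at
p < 1e-4 by default — the threshold is a config knob since no standard
value exists. "MAF > 1 %" is strict; the exon rule is distance from SNP
position to nearest exon base < 200 bp rejects (exactly 200 bp passes).
Within a spacing window, ties in ranking-population MAF break toward the
smaller position for determinism. The four populations are configurable
keys (defaults EAS/EUR/AFR/AMR, with EAS as ranking population); probe GC
is accepted as a precomputed per-SNP value because probe design itself is
a vendor process out of scope here.

## Known limitations

* The scale degeneracy is broken by a parsimony prior, so genuinely
  high-ploidy tumors (ψ ≳ 4 with little allelic asymmetry) would be
  under-called; the `ambiguous` flag marks exactly these cases.
* At purity ≤ 0.2 the signal compresses into the noise floor and scores
  collapse toward 0 — this matches the method's published behaviour and
  motivates the ≥ 30 % purity recommendation.
* Segment boundaries are only as precise as half the SNP spacing; scar
  thresholds (11/15 Mb) are therefore fuzzy at the ±0.1 Mb scale for
  real events sitting exactly on a threshold.
* The Gaussian segment-mean likelihood is a deliberate simplification of
  a full per-site binomial mixture; it is accurate at ≥ 10 sites per
  segment and far cheaper, but underweights segments with very few sites.
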