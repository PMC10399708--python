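# hrdscar

Genomic-scar scoring of homologous recombination deficiency (HRD) from
sparse SNP-panel tumor/normal sequencing.

Tumors that cannot repair double-strand breaks by homologous recombination
(e.g. *BRCA1/2*-deficient ovarian cancers) accumulate characteristic
structural scars. Three validated scar counts quantify this, and their sum
predicts benefit from PARP inhibitors and platinum chemotherapy:

* **HRD-LOH** — loss-of-heterozygosity segments longer than 15 Mb but
  shorter than a whole chromosome;
* **HRD-TAI** — allelically imbalanced regions reaching a sub-telomere
  without crossing the centromere;
* **HRD-LST** — breakpoints between adjacent copy-number regions of at
  least 11 Mb, after smoothing away variation shorter than 3 Mb;
* **HRD score** = LOH + TAI + LST, called positive at the clinical cutoff
  of **42**.

Rather than whole-genome sequencing or SNP microarrays, the scars can be
measured from a small capture panel of common, non-exonic SNPs spaced about
every 50 kb. `hrdscar` implements that whole measurement chain end to end:

1. **Panel design** (`hrdscar.panel_design`) — filter population SNPs by
   minor allele frequency (> 1 % in all four populations), exon distance
   (≥ 200 bp), an exact Hardy–Weinberg test per population, and probe GC
   content (25–75 %); then keep, per 50-kb genomic window, the SNP with the
   highest allele frequency in the designated ranking population
   (East-Asian by default), plus in-silico panel down-sampling.
2. **Tumor simulation** (`hrdscar.simulator`) — synthetic tumors with
   planted LOH/TAI/LST events on a diploid background, per-SNP tumor/normal
   read counts under a purity–ploidy mixture (Poisson depths, binomial
   allele counts), in-silico purity dilution and depth down-sampling.
3. **Allele-specific copy number** (`hrdscar.ascn`) — logR / folded-BAF
   signals, recursive binary segmentation, exhaustive purity–ploidy grid
   search and integer (nA, nB) assignment. For a segment with allele
   copies nA ≥ nB, total t = nA + nB, tumor purity p and ploidy ψ:

   ```
   BAF(p, nA, nB) = (p·nB + (1 − p)) / (p·t + 2(1 − p))
   R(p, ψ, t)     = (p·t + 2(1 − p)) / (p·ψ + 2(1 − p)),   logR = log2 R
   ```

4. **Scar scoring** (`hrdscar.scar_scores`) — the three counts, their sum
   and the binary call, on either truth segments or fitted profiles.
5. **Evaluation** (`hrdscar.evaluation`) — purity-dilution series,
   depth-titration series (50–250×), panel-subset concordance (R²,
   rank-based AUC) and 3-Mb heterozygosity binning.

## Worked example

```python
from hrdscar import grch37, score_hrd
from hrdscar.simulator import (EventSpec, simulate_truth_profile,
                               synthetic_panel, simulate_observations)
from hrdscar.evaluation import run_pipeline

genome = grch37(include_sex=False)
spec = EventSpec(n_loh=8, n_tai=6, n_lst=12, n_decoy=4)
truth = simulate_truth_profile(genome, spec, seed=11, purity=0.6)
print('planted ledger:', truth.ledger, ' true ploidy: %.2f' % truth.ploidy)

panel = synthetic_panel(genome, spacing=100_000, seed=0)
obs = simulate_observations(truth, panel, mean_depth=300.0, seed=12)
profile, scores = run_pipeline(obs, genome)
print('fitted purity: %.2f  ploidy: %.2f' % (profile.purity, profile.ploidy))
print(scores.as_dict())
```

prints

```
planted ledger: {'loh': 8, 'tai': 6, 'lst': 12}  true ploidy: 1.99
fitted purity: 0.60  ploidy: 1.99
{'loh': 7, 'tai': 6, 'lst': 12, 'hrd': 25, 'status': 'negative', 'cutoff': 42}
```

A tumor with 26 planted scars, sequenced at 300× with only 60 % tumor
cells, is recovered with the correct purity and ploidy and 25 of 26 scars
(one 16-Mb LOH segment falls below detection at this purity); the HRD score
of 25 is negative at the cutoff of 42.

The same chain is available from the shell:

```sh
hrdscar simulate --spec spec.yaml --depth 300 --seed 7 --out obs.tsv
hrdscar fit-ascn --obs obs.tsv --out segs.tsv
hrdscar score --segs segs.tsv            # JSON {loh, tai, lst, hrd, status}
hrdscar design-panel --candidates cands.vcf --exons exons.bed --out panel.bed
hrdscar evaluate-dilution --out dilution.tsv
```

## File formats

* **Genome build** — TSV with columns `chrom  length  cen_start  cen_end`
  (a GRCh37 table with UCSC hg19 centromere gaps ships with the package;
  any replacement table may be passed via `--genome`).
* **Observations** — TSV `chrom pos n_ref n_alt t_ref t_alt normal_gt`
  (0-based positions; `normal_gt` is 0 hom-ref / 1 het / 2 hom-alt).
* **Segments** — TSV `chrom start end n_sites logr baf nA nB`, 0-based
  half-open, plus a JSON sidecar with purity/ploidy/log-likelihood.
* **Candidates** — VCF with per-population INFO keys `{POP}_AF` (alt allele
  frequency) and `{POP}_GC` (`hom_ref,het,hom_alt` genotype counts) and
  optional `PROBE_GC`, or an equivalent TSV written by
  `hrdscar.io.write_candidates`.
* **Panels** — BED (single-base intervals, ranking-population MAF as score).

Internally everything is 0-based half-open; VCF input is converted on read.

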