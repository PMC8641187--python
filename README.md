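# sweepkit

Selection-signature scanning for multi-population diploid SNP-chip
cohorts, built as a tested, reusable pipeline:

* **QC** — MAF, per-locus call rate, exact Hardy–Weinberg test
  (Wigginton-style enumeration), plus greedy sliding-window LD pruning
  (`indep-pairwise`-like semantics on genotype r²).
* **Selection scan** — per-locus FST from mean-square components
  `FST = (MSP − MSG) / (MSP + (n_c − 1)·MSG)`, windowed FST
  (ratio-of-sums or mean, default 100 kb windows / 50 kb step), windowed
  nucleotide diversity (default 50 kb / 25 kb), a Δπ differential scan,
  and empirical top-1%/5% outlier windows.
* **Diagnostics** — runs of homozygosity, LD decay over fixed distance
  classes (2.5–160 kb), IBS distances, neighbour-joining trees with
  bootstrap support and Newick output.
* **Annotation** — gene-interval overlap (BED/GFF3) of outlier windows
  and hypergeometric overrepresentation with Benjamini–Hochberg
  correction (GMT term maps).
* **Synthetic cohorts** — a forward Wright–Fisher simulator that emits a
  multi-breed SNP-panel-like cohort (8 breeds in indigenous /
  commercial-meat / commercial-milk groups by default) with known
  selected loci, so every stage is testable offline with ground truth.

## CLI

All stages are exposed via `sweepkit`:

```sh
# simulate a cohort and write PED/MAP, VCF, population map, truth BED,
# gene BED and GMT fixtures
sweepkit simulate --seed 1 --out-dir fixtures/

# individual stages
sweepkit qc   --vcf fixtures/cohort.vcf --pop-map fixtures/populations.tsv \
              --report qc.tsv --keep-list keep.txt
sweepkit fst  --vcf ... --pop-map ... --scheme scheme.yaml \
              --group-a indigenous --group-b commercial_meat --out fst.tsv
sweepkit pi   --vcf ... --pop-map ... --populations native_a,native_b --out pi.tsv
sweepkit roh  --vcf ... --pop-map ... --out roh.tsv
sweepkit ld   --vcf ... --pop-map ... --populations native_a --out ld.tsv
sweepkit tree --vcf ... --pop-map ... --replicates 1000 --out tree.nwk
sweepkit annotate --regions-bed outliers.bed --genes genes.bed \
              --terms-gmt terms.gmt --out genes_hit.tsv

# the whole scan from one YAML config
sweepkit run-all --config run.yaml --seed 1 --out-dir results/
```

`run-all` performs QC once, then for each commercial group vs the
indigenous group: windowed FST with top-1%/5% outliers, per-group
windowed π with a top-1% Δπ scan, and gene annotation of the union of
outlier regions; separately it LD-prunes for the NJ tree/bootstrap and
computes ROH and LD decay per population. A `manifest.json` records
versions, seed, parameters and per-stage row counts. Reruns with the
same seed and config are byte-identical.

Window statistics are written as TSV
(`chrom  start  end  n_loci  value  percentile_rank`, 1-based half-open
intervals); outliers additionally as 0-based half-open BED.

## Notes on conventions

* Dosages count alt-allele copies (0/1/2) with a distinct MISSING code;
  missing calls are never imputed.
* PED input is unpolarised: alt defaults to the minor allele, and an
  allele-reference TSV (written by the fixture writer) fixes the
  orientation for exact round-trips. FST and π are orientation-invariant.
* Estimator knobs: `n_c` is the arithmetic mean of per-subpopulation
  sample sizes by default (Weir–Cockerham form available), and the MSG
  denominator is `(Σ nᵢ) − 1` by default (`Σ (nᵢ − 1)` available).
* Group comparisons default to two pooled subpopulations (s = 2);
  breeds-as-subpopulations is available via `pool_groups=False`.
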