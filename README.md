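# hapflow

Window-based local-ancestry inference, a haplotype-migration statistic,
and EHH-based selection scans (iHS, Rsb) plus single-marker F_ST for
admixed diploid cohorts genotyped on SNP-chip-density panels — with a
synthetic-data generator producing diverged parental breeds and admixed
cohorts with known ancestry tracts.

## What it does

Given phased genotypes for several parental populations ("breeds") and an
admixed cohort:

1. **genodata** — reads/writes phased VCF 4.2, applies a per-population
   MAF filter (site kept if MAF > threshold in *any* population by
   default), and subsets populations.
2. **hapwin** — builds SNP-index windows (30-SNP, non-overlapping or
   15-SNP step) and per-window exact-match haplotype frequency spectra.
3. **lancestry** — a window-level haplotype-copying HMM: per
   non-overlapping 30-SNP window, the emission of an admixed window
   haplotype given breed B averages `eps^mismatch (1-eps)^match` over B's
   panel haplotypes; a Markov chain over windows (stay `1-rho`, else
   redraw from the prior) yields forward–backward posteriors and Viterbi
   tract labels, plus mean / exclusivity-threshold ancestry summaries.
4. **migration** — for each breed and (30-SNP, step-15) window, the
   breed's most frequent haplotype is located in the admixed cohort; its
   expected frequency is `p_B * freq_B` (local ancestry x parental
   frequency), the score is `observed - expected`, standardized per breed
   genome-wide. Positive z = haplotype more common than ancestry
   predicts.
5. **selstats** — EHH decay curves, iHS (trapezoid-integrated EHH,
   standardized within derived-allele-frequency bins), Rsb
   (allele-agnostic site-EHH log-ratio between populations, median
   centered), Hudson/Nei F_ST, and a candidate-region caller (>= 3
   consecutive significant SNPs per 1 Mb).
6. **simpop** — Balding–Nichols parental panels, Markov ancestry-tract
   admixture with one donor haplotype per tract, and planted
   haplotype-frequency shifts for power studies.
7. **pipeline** — YAML-configured end-to-end run with deterministic
   outputs and provenance.

## CLI

```bash
hapflow simulate --config sim.yaml --seed 7 --out simdir/
hapflow filter --vcf cohort.vcf --manifest manifest.tsv --maf 0.01 --out filtered.vcf
hapflow windows --vcf filtered.vcf --manifest manifest.tsv --size 30 --step 15 --out spectrum.tsv
hapflow ancestry --vcf filtered.vcf --manifest manifest.tsv --out ancestry.tsv
hapflow run --config run.yaml          # full pipeline -> migration.tsv, ihs.tsv, ...
```

The sample manifest is a TSV with columns `sample_id`, `population`,
`role` (`parental_panel` or `admixed`). A minimal `run.yaml`:

```yaml
out_dir: myrun
seed: 7
simulate:            # or: vcf: cohort.vcf / manifest: manifest.tsv
  n_per_breed: 35
  n_admixed: 100
  n_sites: 2000
  chrom_lengths: [100000000]
  admix_props: [0.53, 0.32, 0.15]
maf_threshold: 0.01
window_size: 30
scan_step: 15
z_threshold: 3.0
```

## Conventions & caveats

- bp positions are 1-based (VCF); internal indices 0-based half-open;
  BED exports 0-based half-open.
- Missing calls: allowed on input; window haplotypes containing a
  missing call are excluded from spectra; in EHH a missing call breaks
  haplotype identity.
- The ancestral-allele assignment for iHS defaults to REF-as-ancestral
  and flips signs if wrong — set it explicitly when known.
- The migration score's default sign convention is observed − expected;
  the alternative literal form `p(B)·freq(K|B) − freq(B)` is available
  (`sign="literal"`) but is not the convention used in reports.
- The "minimum probability" ancestry summary uses an exclusivity
  threshold (default 0.95) — one interpretation of a single-origin
  summary; the mean summary feeds the migration scan by default.
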