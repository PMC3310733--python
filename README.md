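# mirsel

Allele-aware miRNA target-site scanning and population-genetic selection
analysis at polymorphic 3'UTR sites, exercisable end to end on synthetic
data with known ground truth.

The pipeline detects SNPs where one allele completes a canonical miRNA seed
match (8mer / 7mer-m8 / 7mer-A1 / optional 6mer) while the other breaks it,
then asks whether such allele-dependent binding sites are enriched among
highly population-differentiated loci and whether individual candidates
carry within-population selection signatures:

- **per-SNP F_ST** (Weir–Cockerham estimator, multi-population),
- **F_ST-bin enrichment** of target-site SNPs over a background SNP set,
  with a resampling null and an upper hypergeometric tail probability for
  the extreme-differentiation bin (F_ST ≥ 0.5 by default),
- **hitchhiking control**: candidates in LD (r² ≥ 0.5 within ±500 kb, per
  population) with annotated functional variants are excluded,
- **within-population scans**: windowed Fay–Wu H, EHH decay curves and iHS
  (standardized within derived-frequency bins), and a composite-likelihood-
  ratio (CLR) sweep scan against a panel-wide background site frequency
  spectrum,
- **latitude clines**: Pearson correlation of derived allele frequency with
  absolute latitude across populations, ranked against a genome-wide
  empirical correlation distribution (optionally restricted to high-F_ST
  SNPs).

A first-class synthetic-data module generates every input the pipeline
reads — multi-population phased panels with Balding–Nichols differentiation
and distance-decaying LD, structurally injected selective sweeps, UTRs with
truth-labelled planted seed sites, and latitude-cline frequency tables —
always emitting ground truth separately from the pipeline inputs.

## CLI

```sh
mirsel simulate --profile full --seed 7 --out fixture/      # synthetic dataset + truth/
mirsel run --input-dir fixture --seed 7 --out results_run/  # full pipeline
mirsel scan --utrs fixture/utrs.fasta --snp-table fixture/utr_snps.tsv \
    --families fixture/families.tsv --allow-6mer --out scan_out/
mirsel stats --vcf fixture/panel.vcf --samples fixture/samples.tsv --stat fst --out stats_out/
mirsel ld --vcf fixture/panel.vcf --samples fixture/samples.tsv --focal snp010 --out ld_out/
mirsel cline --freqs fixture/cline_freqs.tsv --populations fixture/cline_populations.tsv --out cline_out/
```

Profiles: `null`, `enriched`, `sweep`, `cline`, `full`.  `mirsel run` also
accepts `--config config.yaml` (any `PipelineConfig` field; CLI flags
override).  Exit codes: 0 ok, 1 data error, 2 config error.  Every run
writes the resolved config and a JSON stage log beside the result tables;
identical inputs and seed give byte-identical outputs.

## Layout

| path | contents |
| --- | --- |
| `src/mirsel/io_formats.py` | VCF/FASTA/TSV readers and writers, domain types, coordinate conventions |
| `src/mirsel/simulate.py` | Balding–Nichols panels, sweep injection, site planting, latitude clines |
| `src/mirsel/target_scan.py` | 15-nt polymorphic windows, per-allele site classification, verdicts |
| `src/mirsel/popgen.py` | F_ST, unfolded SFS, Fay–Wu H, EHH/iHS, CLR sweep scan |
| `src/mirsel/enrichment.py` | F_ST binning, enrichment scores, bootstrap null, hypergeometric tail |
| `src/mirsel/ld.py` | pairwise D/D'/r²/LOD, hitchhiking filter, regional LD profiles |
| `src/mirsel/cline.py` | latitude correlations and empirical percentiles |
| `src/mirsel/pipeline.py`, `cli.py` | orchestration, fixtures, `mirsel` command |
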