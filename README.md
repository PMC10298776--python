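# caqtlkit

Cell-type-resolved chromatin accessibility QTL (caQTL) analysis toolkit:

- **Joint caQTL mapping** (`caqtlkit.caqtl`): a single cis allelic effect π
  drives both a negative-binomial model on total peak fragment counts and a
  beta-binomial model on allele-specific read counts at heterozygous
  samples (with reference-mapping bias ψ and allele-flip error ∂). Testable
  pairs require mean peak coverage > 5 reads, a variant inside the peak or
  a peak within ±10 kb, and ≥ 2 heterozygous samples. Genome-wide control
  uses Benjamini–Hochberg q-values of per-peak lead variants compared
  against genotype-permuted reruns (empirical FDR, 2 permutations by
  default), followed by ψ/∂ QC filters and genotype-class diagnostics.
- **Heterogeneity** (`caqtlkit.heterogeneity`): median-of-ratios + log2
  normalization, genotype × cell-type interaction ANOVA (nested-model F),
  pairwise Spearman correlation of allelic effects, and Storey bootstrap
  π1 sharing estimates.
- **Co-accessibility** (`caqtlkit.coaccess`): k-nearest-neighbor cell
  aggregation (k = 30), distance-penalized graphical-lasso partial
  correlations in 1 Mb windows, link gates (score > 0.05, distance > 10 kb,
  replication in ≥ 4 samples), promoter annotation (TSS ± 2 kb), caQTL →
  promoter linkage, distal-effect propagation tests (population-only model,
  FDR 20%) and loop-overlap Fisher enrichment.
- **Fine-mapping** (`caqtlkit.finemap`): LD r² against a reference panel
  (±2.5 Mb), r² > 0.1 pre-filter, Wakefield approximate Bayes factors
  (prior variance W = 0.04), per-signal PPA and 99% credible sets.
- **Trait enrichment** (`caqtlkit.traitenrich`): credible-set variant
  annotation with caQTL status, and cumulative-PPA enrichment in caQTL
  peaks against 1,000 seeded background draws.
- **Motif disruption** (`caqtlkit.motif`): PFM → PWM construction, exact
  score-distribution tail p-values by dynamic-programming convolution,
  allelic disruption calls (bound at p < 5×10⁻⁴, strong/weak by scaled
  score difference), and one-tailed binomial per-motif enrichment with BH
  correction. A small bundled toy PFM set stands in for a motif database.
- **Synthetic data** (`caqtlkit.synthdata`): a first-class generator for
  everything the pipeline consumes — founder-haplotype LD-block genotypes,
  per-cell-type count tensors with allelic counts, single-cell matrices
  with embeddings and planted co-accessibility modules, GWAS summary
  statistics with planted causal variants — plus a ground-truth ledger.
- **Pipeline & I/O** (`caqtlkit.pipeline`, `caqtlkit.io`): strict
  biallelic-SNV VCF and BED3+ readers/writers (internal coordinates
  0-based half-open), TSV/MTX tensors, and a deterministic, manifest-writing
  orchestrator.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the simulation-based acceptance criteria
(FDR control, parameter recovery, oracle equivalences, calibration and
power checks, end-to-end determinism); the other files are per-module unit
and property tests. The full suite takes ~10 minutes on one CPU.

## CLI

Every stage is a subcommand of the `caqtlkit` entry point and operates on a
run directory:

```sh
caqtlkit simulate  --outdir run1 --seed 7          # synthetic cohort
caqtlkit map-caqtl --outdir run1 --seed 7 --fdr 0.10 --permutations 2
caqtlkit heterogeneity --outdir run1 --seed 7
caqtlkit coaccess  --outdir run1 --seed 7 --k 30 --threshold 0.05
caqtlkit finemap   --outdir run1 --seed 7 --w 0.04 --r2-min 0.1
caqtlkit enrich    --outdir run1 --seed 7 --n-draws 1000
caqtlkit motif     --outdir run1 --seed 7
caqtlkit run       --outdir run1 --seed 7          # all stages + manifest
```

A YAML config (`--config run.yaml`) can set any `RunConfig` field,
including `sim:` overrides for the synthetic cohort. Reruns with the same
config and seed are bit-identical; `manifest.json` records parameters and
output hashes.

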