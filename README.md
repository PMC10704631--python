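# strainshift

Strain-level metagenomic profiling of paired host-state microbiome samples.
The package implements, as a tested reusable pipeline, the analysis of a
paired two-state (nurse/forager) gut-microbiome study design:

- **Absolute bacterial loads** from qPCR standard curves
  (`copies = 10^((Ct − intercept)/slope)`), normalized per ng of total DNA.
- **Species profiling from terminus coverage**: replicating genomes show a
  coverage gradient from the replication origin to the terminus; a
  two-segment piecewise-linear regression over single-copy core-gene
  positions infers the terminus read depth (with a median fallback when the
  fit is implausible), which becomes the relative-abundance proxy.
  Absolute abundance = proportion × load; paired log2 fold changes,
  phylotype aggregation, and Shannon diversity within phylotypes.
- **Strain-level SNV statistics** from pooled per-site allele counts: an
  allele is detected at ≥2 reads and ≥1% frequency; a site is polymorphic
  when ≥2 alleles are detected (reference-independent); polymorphic-site
  fractions per filtered core genome, cumulative diversity curves over 10
  random sample orders, and pairwise distances
  `1 − shared fraction` where a site counts as shared only when the two
  samples' detected allele sets intersect in ≥2 alleles.
- **Differential gene content**: contig-to-species binning by ORF hit
  voting (80% majority / 10% exclusive rules), orthologous-group (OG)
  coverage aggregation, normalization of single-copy core OGs to 10000 per
  species and sample, paired Wilcoxon + q-values + |log2FC| ≥ 1 calling,
  and COG-category Fisher enrichment.
- **Statistics**: exact paired Wilcoxon signed-rank (enumeration up to
  n = 25, midranks under ties), Storey q-values with BH fallback, Fisher's
  exact test, Bray–Curtis, classical PCoA, and marginal-term PERMANOVA
  (`Distance ~ Host + Location`, 999 permutations) with ω² effect sizes.
- **Synthetic data**: a fully seeded generator producing every pipeline
  input with known ground truth — paired colony design, state-dependent
  abundance shifts, V-shaped Ori→Ter coverage gradients, strain-mixture
  allele pileups with sequencing error, planted differential OGs, and qPCR
  Cts from true copy loads. With all noise sources off, every downstream
  stage recovers the planted parameters exactly (tested).

## Run the pipeline

```bash
# everything end-to-end on a synthetic scenario
strainshift run --seed 7 --outdir out/

# individual stages (each reads its declared inputs from the config)
strainshift simulate   --config config.yaml
strainshift quantify   --config config.yaml
strainshift community  --config config.yaml
strainshift snv        --config config.yaml
strainshift genecontent --config config.yaml
strainshift stats      --config config.yaml
```

The YAML config mirrors `strainshift.pipeline.PipelineConfig`; every
published threshold is pre-filled (alignment match length > 50, ≤ 5
mismatches in SNV mode, gene coverage ≥ 10×, species terminus coverage
> 20×, allele detection ≥ 2 reads and ≥ 0.01 frequency, contigs ≥ 500 bp
and k-mer coverage ≥ 1, complete ORFs ≥ 300 bp, blast evalue < 1e-5 /
pident > 50 / qcovs > 50, core-OG normalization constant 10000,
significance at q < 0.05 and |log2FC| ≥ 1, 999 permutations, 10 random
sample orders). Unknown keys are rejected. A `manifest.json` with the
version, seed and all parameter values is written per run; identical seeds
give byte-identical outputs.

Coordinates are 0-based half-open internally; VCF is 1-based at the
boundary; BED-like tables are 0-based half-open.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: worked-example
fidelity of the allele-sharing rule, machine-precision core-OG
normalization, oracle equivalence (brute-force set enumeration,
hypergeometric enumeration, 2^n sign enumeration, direct PERMANOVA SS,
exhaustive-grid segmented fits), parameter-recovery suites on seeded noisy
simulations, null calibration of Wilcoxon and PERMANOVA, strain-turnover
recovery, and the deterministic end-to-end smoke test.

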