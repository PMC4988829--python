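# tailte

Analysis toolkit linking mRNA poly(A)-tail length to translational
efficiency (TE) across developmental stages and genotypes, plus a synthetic
cohort generator that emulates poly(A)-tag, ribosome-footprint (RPF) and
RNA-seq inputs so every stage of the pipeline can be verified without
external data.

## What it does

- **`tailte.synthetic`** — multi-stage, multi-genotype cohort simulation:
  per-gene mean tails with unimodal per-molecule tail distributions (gamma),
  stage-dependent tail→TE coupling that can be switched off per stage,
  planted temporal TE profiles, and genotype effects (global tail shrinkage
  with a spared set; nulled transition changes for planted target sets; a
  partially responsive subset). Ground truth is recorded for recovery tests.
- **`tailte.gene_models`** — representative transcript selection from
  refFlat annotations, poly(A)-tag filtering (tail ≥ 20 nt), cleavage-site
  calling (≥ 2 tags between stop codon and neighboring same-strand TSS),
  greedy tandem-isoform collapsing (60 nt window, 4100 nt 3'-UTR cap) and
  distal 3'-end extension.
- **`tailte.quantify`** — per-gene tail summaries pooled across tandem
  isoform ends, RPM/RPKM, log2 TE with a 1-read pseudocount rule and
  median centering, stage-appropriate quantification cutoffs, and
  between-stage change tables (relative and absolute tail changes).
- **`tailte.coupling`** — Spearman rank correlations (average-rank ties),
  binned-median TE summaries with the [70,80) vs [30,40) nt fold ratio,
  change-coupling on relative or absolute scale, and an RNA-abundance vs
  tail-length selection-bias diagnostic.
- **`tailte.dynamics`** — model-profile clustering of short TE time series:
  exhaustive enumeration of integer profiles with bounded unit change, a
  ≥ 0.5 log2 eligibility filter, correlation-based assignment, and a
  permutation/binomial enrichment surrogate with Bonferroni correction.
- **`tailte.contrasts`** — dependent-set definition (≥ 4-fold in both
  comparisons), ≥ 50 % tail-shortening census, Wilcoxon rank-sum set-shift
  tests (exact enumeration for small groups, tie/continuity-corrected
  normal approximation otherwise) and footprint concordance with
  pseudocounted zeros.
- **`tailte.io` / `tailte.cli`** — refFlat and TSV dialect readers/writers
  with provenance headers, flat key=value config files, fixture layout, and
  the `tailte` command-line pipeline.

## CLI

```sh
# generate a synthetic fixture from a flat config file
tailte simulate --config examples/sim.cfg --out fixture/ [--seed 7]

# re-annotate 3' ends from a refFlat annotation and a tag table
tailte annotate --refflat genes.refflat --tags tags.tsv --out models/

# run analysis stages against a fixture directory
tailte quantify  --fixture fixture/ --out results/
tailte coupling  --fixture fixture/ --out results/
tailte dynamics  --fixture fixture/ --out results/
tailte contrasts --fixture fixture/ --out results/
tailte all       --fixture fixture/ --out results/
```

A simulation config is a flat `key = value` file, e.g.

```
n_genes = 2000
stages = s11,s13,egg,gast
coupling_beta = 1.2,1.2,1.2,0.0
depth_rna = 2000000
depth_rpf = 2000000
depth_tags = 600000
seed = 7
genotypes = wispy,png,smg
png.n_up = 30
png.n_down = 40
profile_classes = 0|1|2|1:0.1:1.0
```

Exit codes: 0 success, 1 stage failure, 2 invalid configuration/usage.
Outputs are plain TSVs with `# key: value` provenance headers; a run log
records versions, seeds, cutoffs and every centering constant, and repeated
runs on the same fixture are byte-identical.

Real-data mode consumes processed tables of the same shapes (refFlat gene
models; per-sample tag tables with `chrom site strand tail_length sample`
columns; long count tables with `gene_id sample rna_count rpf_count`); no
download helpers are included.

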