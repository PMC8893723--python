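# fruitstrat

Toolkit for comparative developmental transcriptomics of fruiting-body-forming
fungi. It reimplements, as a tested and reusable pipeline, the computational
core of a multi-species fruiting-body RNA-seq analysis:

- **devexpr** — FPKM computation and classification of developmentally
  expressed genes (fold-change between non-VM stage/tissue groups, FPKM > 4
  detectability floor, vegetative-mycelium exclusion).
- **phylostrat** — relative gene ages from orthogroup species sets on a rooted
  species tree (MRCA projected onto the numbered root→focal path),
  per-stage transcriptome age index (TAI), Fisher + Benjamini–Hochberg age
  enrichment, and a Mann–Kendall trend test (exact for n ≤ 10).
- **allele_expr** — Hamming-distance assignment of reads to two parental
  nuclei with the three indecisiveness rules, AS ratios with masking
  (FPKM < 2, < 16 decisive reads, > 80% indecisive), EE/S2/S4 classification by
  replicate geometric means, and chromosome/nuclear read ratios (CRR/NRR).
- **variant_partition** — partitioning of observed read bases into
  allele-specific markers vs. RNA-editing/technical candidates (Phred ≥ 30),
  with VRS/RS/RVF candidate filters and A-to-I (A→G) compatibility scoring.
- **orthology** — asymmetric coverage filtering of hit tables, Markov
  clustering (inflation 2.0, Nident/qlen weights), reciprocal-best-hit
  orthogroups with a spurious-member filter, conserved-orthogroup
  classification, and the shared vs. CM-specific split against a
  simple-development outgroup.
- **synthetic** — seed-deterministic generators for every input with planted
  ground truth (stage-structured lognormal expression, binomial two-nucleus
  allele counts, reads over SNP haplotypes, orthogroup birth/loss on the
  species tree).
- **core_io / config / pipeline / cli** — TSV/VCF/Newick/hit-table I/O, one
  YAML config holding every threshold (defaults are the published values), and
  a digest-checkpointed end-to-end runner.

## CLI

All stages are exposed under one executable:

```sh
fruitstrat run --config run.yaml          # full synthetic pipeline + manifest
fruitstrat simulate expression --n-genes 2000 --seed 1 --out expr.tsv
fruitstrat devexpr --expression expr.tsv --design expr.design.tsv --fc 4 --out dev.tsv
fruitstrat age --orthogroups ogs.tsv --tree tree.nwk --focal sp9 --out ages.tsv
fruitstrat tai --expression expr.tsv --design expr.design.tsv --ages ages.tsv --out tai.tsv
fruitstrat enrich --calls dev.tsv --ages ages.tsv --out enrichment.tsv
fruitstrat ase --counts counts.tsv --design expr.design.tsv --out as_ratio.tsv
fruitstrat variants --observations obs.tsv --out partitioned.tsv
```

A config file is plain YAML; any subset of `fruitstrat.config.PipelineConfig`
fields may be given (`seed`, `n_genes`, `output_dir`, thresholds, …).
`fruitstrat run` writes every stage output plus `manifest.json` with sha256
digests; reruns skip stages whose inputs are unchanged.

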