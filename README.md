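# linecrossqtl

QTL mapping for two-line (inbred or outbred) line crosses: a pipeline of

- **cross_data** — a validated in-memory cross object (pedigree, phenotypes,
  genotypes, genetic map, cross attributes) with plain-text TSV dialects and a
  simplified CRI-MAP-style `.gen` reader/writer;
- **sim_cross** — an F0→F1→F2/BC simulator with Haldane (no-interference)
  meioses, per-line marker allele models, QTL with within-line segregation and
  epistasis, and full descent truth (founder-homolog labels everywhere);
- **line_origin** — hidden-Markov-model posterior probabilities of founder-line
  origin at regular grid positions (4 ordered states for F2, 2 for BC),
  forward filtering–backward sampling of joint origin paths, and an
  exhaustive-enumeration oracle for small instances;
- **ls_scan** — single-locus least-squares genome scans on the line-origin
  predictors, a two-locus 4-df epistasis scan, and genome-wide
  maximum-statistic permutation thresholds;
- **noia** — orthogonal genetic-effect estimation for arbitrary genotype
  frequencies, change of reference population, and Kronecker multi-locus
  genotype–phenotype maps;
- **fia** — Monte-Carlo locus IBD matrices (descent sampling conditioned on
  marker data), a REML one-component variance model, a standardized
  score-statistic genome scan with permutation thresholds, and a
  fixed-vs-segregating REML log-likelihood ratio;
- **experiments** — the seeded calibration studies behind the acceptance
  suite.

Autosomes and the homogametic sex chromosome are supported; heterogametic-sex
individuals are excluded from sex-chromosome inference.

## CLI

All commands live under `lcq`:

```sh
lcq sim     --config sim.toml --out DIR          # simulate a cross (+ truth.tsv)
lcq convert --from crimap --gen F.gen --map M.tsv --out DIR
lcq probs   --in DIR --step 1.0 --error-rate 0.001 --out probs.tsv
lcq scan    --in DIR --trait y --covar sex --step 1 --out scan.tsv [--plot scan.png]
lcq scan2   --in DIR --trait y --step 5 --pair-step 10 --out scan2.tsv
lcq perm    --in DIR --trait y --n 1000 --seed 1 --quantiles 0.95,0.99
lcq noia    --in DIR --position 1:50 --trait y --ref f2 --out noia.tsv
lcq fia     --in DIR --trait y --step 2 --mc 200 --perm 1000 --seed 1 --out fia.tsv
```

`DIR` holds the tabular file set (`pedigree.tsv`, `genotypes.tsv`, `map.tsv`,
`phenotypes.tsv`, `attributes.txt`) written by `lcq sim`, `lcq convert`, or
`cross_data.write_cross`. File dialects are documented in
`linecrossqtl/cross_data.py`.

Example `sim.toml`:

```toml
seed = 1
n_offspring = 400
cross_type = "F2"
chromosomes = [["1", 100.0, 21, "autosome"]]

[[qtl]]
chromosome = "1"
position = 50.0
a = 0.5
```

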