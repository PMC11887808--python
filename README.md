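# mitolineage

Single-cell mitochondrial DNA (mtDNA) heteroplasmy dynamics: a tested,
reusable pipeline for studies that sequence the mitochondrial genome of
individual cells in technical replicate — e.g. hiPSC lines and the
astroglia and neurons differentiated from them in brain organoids — and
ask where mtDNA single-nucleotide variants (mtSNVs) come from, how
selection acts on them during differentiation, and which cells share a
clonal origin.

## What it does

Starting from per-cell, per-run position × base allele-count tables on a
circular reference genome, the pipeline provides:

- **Replicate-concordant variant calling.** The heteroplasmy fraction
  (HF) of an allele is its read fraction, HF = alt reads / depth. A
  candidate mtSNV is accepted only when HF > 0.005 (strictly) in *every*
  independent sequencing run of the cell — low-frequency artifacts do not
  recur across independent PCR + library + sequencing rounds. Calls in
  homopolymer tracts or below a per-run depth floor are filtered; an
  exact binomial error test P(X ≥ k | depth, e/3) per run is available
  as an evidence column, and replicate agreement is summarized by the
  OLS R² of run-2 HF on run-1 HF.
- **Lineage classification.** Against the founder hiPSC variant set of a
  line, each organoid-side variant is *shared* or *de novo*; each
  founder variant is *transmitted* or *lost*. Selection during
  differentiation is quantified per founder variant per cell by the
  absolute shift aHS = HF_cell − HF_founder and the normalized shift
  nHS = aHS/(1 − HF_founder) for gains, aHS/HF_founder for losses,
  bounded in [−1, 1].
- **Strand-aware mutational signatures.** Substitutions are reduced to
  the 96 pyrimidine-centered trinucleotide classes (purine-reference
  changes complemented onto the heavy strand), normalized per strand by
  the reference's trinucleotide context frequencies, and correlated
  (Pearson, n = 96) against a 30-signature catalog.
- **Clonal structure.** The cell × variant HF matrix is clustered
  hierarchically (Euclidean / complete linkage by default; Newick
  export); entries strictly above the conventional pathogenicity
  threshold HF > 0.6 are flagged with their genomic-region annotation
  and clades are scored for flagged-variant carriers.
- **A statistical battery** mirroring the study designs this serves:
  Wilcoxon rank-sum, two-sample Kolmogorov–Smirnov, Fisher's exact
  (Monte-Carlo for r×c), one-way ANOVA with Tukey HSD, ECDFs.
- **A synthetic data generator.** Per-condition founder clones with
  heteroplasmic variants evolve through clonal-expansion and
  differentiation divisions by Wright–Fisher binomial resampling of N
  mtDNA copies (mutant copy weight 1 + s, so E[p′] = p(1+s)/(1+ps)),
  acquire Poisson de novo mutations over a 96-class signature, and are
  sequenced in replicate runs with lognormal per-cell coverage
  (mean 2515×, heavy right tail), Poisson per-site depth and a uniform
  miscall model. Ground truth (origin, true HF, signature class,
  synthetic pathogenicity score) is emitted alongside.

## Worked example

```
mitolineage all --demo --seed 1 --out demo_run
```

runs the full pipeline on a small synthetic cohort (30 cells, 3 kb
genome, two conditions × three cell types) and prints:

```
mitolineage 0.1.0 end-to-end summary
seed=1 config_hash=a07e9302136a

seed: 1
config_hash: a07e9302136a
n_calls_pass: 189
replicate_r2: 0.9851985917377719
founder_size_ctrl: 8
founder_size_mutant: 7
mean_nhs: -0.5807746176901183
mean_frac_de_novo: 0.12172619047619046
top_signature: {'ctrl.astroglia': 'S11', 'ctrl.ipsc': 'S03', 'ctrl.neuron': 'S09', 'mutant.astroglia': 'S06', 'mutant.ipsc': 'S28', 'mutant.neuron': 'S21'}
n_high_hf_flags: 0
n_tests: 13
```

Reading this: 189 mtSNV calls passed the both-run HF > 0.005 rule;
per-run HFs agree with R² ≈ 0.99, the hallmark of real (not artifact)
low-level heteroplasmy; the control and mutant founder hiPSC lines carry
8 and 7 variants; the mean normalized heteroplasmy shift across founder
variants in differentiated cells is −0.58 (the demo's defaults apply
negative selection to founder variants during differentiation, and
variants drifting below the detection threshold register as losses); and
~12% of organoid-side calls per cell are de novo. Per-stage TSVs
(calls, lineage classes, shifts, spectra, signature correlations, HF
matrices, dendrograms, flags, test results) land in `demo_run/`, each
with `#key=value` metadata headers carrying the version, config hash and
seed; identical config + seed reproduces them byte for byte.

The same stages are importable as a library (`mitolineage.calling`,
`.lineage`, `.signatures`, `.clonal`, `.stats`, `.simulate`) and as
separate subcommands (`simulate`, `call`, `lineage`, `shift`,
`signatures`, `clonal`, `stats`, `report`).

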