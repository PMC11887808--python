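# Methods

## The problem setting

Each human cell carries hundreds to thousands of mtDNA copies; a variant
present on a fraction of them is *heteroplasmic*, and its heteroplasmy
fraction (HF) changes across cell divisions through random segregation
(drift), replication advantage or disadvantage (selection), and new
mutation. Single-cell mtDNA sequencing in duplicate runs makes HFs as
low as 0.5% callable, which opens three questions this package
operationalizes: which variants in differentiated cells were inherited
from the founder stem-cell clone (shared) versus acquired later
(de novo); whether founder variants were selected against during
differentiation (heteroplasmy shift); and which cells share a clonal
origin (HF-matrix clustering).

## Variant calling model

HF is estimated per site and alternative base as alt reads / depth. The
concordance rule accepts a site/alt only when HF strictly exceeds the
threshold (default 0.005) in **every** replicate run. Rationale: a
miscall process with per-base error e sends e/3 of its mass to one
specific alternative base; at depth d the chance that the same base
exceeds the threshold in two *independent* library preparations is the
square of a single-run binomial tail, which at e = 10⁻³ and d = 2500 is
~10⁻²² per site. The same product of exact binomial tails,
Π_runs P(X ≥ k_run | d_run, e/3), is exposed as an optional per-call
evidence column; it replaces a full probabilistic replicate caller with
the concordance rule that drives all downstream analysis.

Filters: homopolymer tracts (runs of one base ≥ `min_run`, default 5,
including runs across the circular origin) are masked because they are
enriched for sequencing artifacts; a per-run depth floor (default 50)
keeps HF = 0.005 resolvable (at depth < 200 a single read exceeds it).
Whether a boundary HF of exactly 0.005 calls: it does not — the rule is
strict (>), and likewise the pathogenicity flag threshold HF > 0.6.
Multi-allelic sites are evaluated per alternative base independently.
The merged HF of a call is the arithmetic mean of per-run HFs (recorded
in the output header so an alternative merge can be substituted).

## Lineage classes and the heteroplasmy shift

The founder set of a line is the union of passing calls over its hiPSC
cells, keyed on (position, alt) only; its per-variant HF is the mean
over carrier cells. Organoid-side calls in the founder set are *shared*,
others *de novo*; founder variants re-detected in ≥ 1 differentiated
cell are *transmitted*, otherwise *lost* (line-wide definition; per-cell
records are also emitted). Per founder variant and differentiated cell:

    aHS = HF_cell − HF_founder
    nHS = aHS / (1 − HF_founder)   if aHS ≥ 0
        = aHS / HF_founder         if aHS < 0

nHS ∈ [−1, 1] by construction (−1 complete loss, +1 fixation) and
removes the founder-HF dependence of the absolute shift. A founder
variant undetected in a cell contributes HF_cell = 0 by default (loss is
the signal of interest); the alternative — omitting such records — is a
flag. Note that nHS is *not* mean-zero under pure drift when
HF_founder ≠ 0.5: losses are divided by HF_founder and gains by
1 − HF_founder, and the detection threshold converts deep drift
excursions into exact losses. Selection inference therefore always
compares against a matched neutral simulation arm rather than against
zero (the validation experiment does exactly this).

## Mutational signatures

A substitution whose reference base is a pyrimidine is classified on the
light strand (the FASTA strand — a declared convention, recorded in
output metadata); purine-reference substitutions are complemented, their
context reverse-complemented, and attributed to the heavy strand. The 96
classes are ordered (C>A, C>G, C>T, T>A, T>C, T>G) × 5′ flank × 3′ flank
lexicographically. With normalization on, each strand's class counts are
divided by that strand's pyrimidine-centered trinucleotide context
frequency in the reference before pooling; the pooled vector is
renormalized to sum 1. Both pooled and per-strand tallies are kept,
since either convention is defensible. Catalog comparison is a Pearson
correlation over the 96 paired rates with the usual t-approximation
p-value (n = 96), ranked descending with name tie-breaks. The packaged
30 × 96 catalog is **synthetic** (Dirichlet rows, fixed seed, row sums
1) — it exercises the machinery and the recovery experiments; any
row-stochastic CSV in the same layout (e.g. a COSMIC-v2 table obtained
separately) can be substituted via `--catalog` / `catalog_path`.

## Clonal clustering

The cell × variant matrix holds merged HFs with 0 for not-called
(consistent with low-HF biology; a mask-missing mode exists for
sensitivity analysis). Clustering is agglomerative on Euclidean
distance with complete linkage — configurable to average linkage or
correlation distance — with deterministic tie-breaking by input order;
dendrograms serialize to Newick. A variant *defines* a clade when all of
the clade's cells and no others carry it above the flag threshold.
Flat cuts are by user-supplied k or height; no automatic model selection
is attempted.

## The synthetic data generator

The generator emulates a duplicate-run single-cell mtDNA study of
hiPSC-derived organoids. Structure: one founder clone per condition
carrying `n_founder_variants` (default 6) variants at HFs drawn
uniformly from (0.02, 0.35); every sampled cell descends from its
founder independently through `t_expansion` (default 20) neutral
expansion divisions, and differentiated cells through a further
`t_differentiation` (default 30) divisions with type-specific copy
number, mutation rate, and per-class selection. Per division each
variant's copy count is resampled Binomial(N, p(1+s)/(1+ps)) —
independent per variant (infinite-sites simplification; linkage between
co-occurring variants is not modeled). New mutations arrive
Poisson(μ) per division, enter at one copy (HF = 1/N, single-molecule
origin), and their sites are drawn by sampling a 96-class from the
signature weights then a uniform matching-context position; collisions
re-draw. Copy number is constant within a phase (no replication
dynamics); defaults place neurons above astroglia and mutant astroglia
lowest (ipsc 500, astroglia 450, mutant astroglia 350, neuron 700).

Sequencing: one mean coverage per cell from a lognormal with mean
`depth_mean` = 2515 and sdlog 1.0 (meanlog = ln(2515) − 0.5), giving the
heavy right tail and a realistic low-coverage minority (a few cells in
the tens of reads); per run and site, depth is Poisson(coverage), reads
are multinomial over the cell's true allele mix, and each read miscalls
to a uniformly chosen other base with probability `error_rate`
(default 10⁻³). Runs are independent draws.

Defaults for what the data themselves cannot pin down — the per-division
mutation rate (μ: ipsc 0.2, astroglia 0.4, mutant astroglia 0.8,
neuron 0.3) and selection (s = −0.05 on founder-era variants during
differentiation, 0 on post-differentiation variants; expansion
neutral) — are illustrative: they reproduce the qualitative study
conditions (negative shift of founder variants, more de novo burden in
mutant astroglia, de novo HFs below shared HFs) and are recorded as
such in the truth-table header. Cohort defaults: 74 hiPSC, 70
astroglia, 62 neuron cells split over two conditions; duplicate runs.

What the generator does **not** emulate: PCR duplicates, strand bias,
alignment or NuMT artifacts, mtDNA rearrangements, copy-number
regulation, or shared genealogy between sampled cells beyond the
founder. Tests passing on this generator therefore demonstrate the
correctness of the algorithms under the stated stochastic model, not
robustness to those real-data artifacts.

Determinism: one master seed; per-cell substreams are spawned from a
`SeedSequence` keyed by sorted cell id, so output is bit-reproducible
and stable against unrelated config changes.

## Validation experiments and problem sizes

`mitolineage.validation` (run by `scripts/acceptance.py` and the
whole-pipeline test module) measures:

- **Caller specificity/sensitivity** — 50 variant-free cells × 16,500
  sites, depth 2500, e = 10⁻³, duplicate runs, vs the closed-form
  3·P(Binom(2500, e/3) > 12.5)² per site; sensitivity at true HF 0.05
  over 10⁴ sites vs the analogous tail product (≥ 99% expected).
- **Neutral drift law** — 2,000 lineages, N = 500, t = 20, p₀ = 0.3;
  Var(HF) vs p₀(1−p₀)(1−(1−1/N)ᵗ) and the martingale mean.
- **Selection recovery** — 10 seeded replicates of s = −0.1 on founder
  variants (200 differentiated cells) vs a neutral arm of equal size,
  through the full sequence→call→founder-set→shift path; success =
  negative mean nHS and two-sample KS p < 0.01 between arms.
- **Signature recovery** — 100 replicates of 500 de novo variants drawn
  from one catalog row on a 16,569-bp genome; success = that row ranks
  first. The raw (unnormalized) spectrum is correlated here because the
  generator samples classes directly from the row.
- **Clonal recovery** — 20 replicates planting an HF-0.7 variant into 8
  of 24 astroglia; success = the members form exactly one flat cluster
  at k = 2 and all are flagged by HF > 0.6. Standard QC applies first:
  the planted site avoids the homopolymer mask (variants there are
  excluded by design) and cells with mean coverage < 100× are excluded
  from lineage tracing (they cannot be genotyped under the depth
  filter).
- **Type-I calibration** — 10⁴ null simulations per test at α = 0.05.
  Sample sizes sit in each test's near-continuous regime so the nominal
  level is meaningful: rank-sum 50/50, KS 100/150 (unequal sizes — at
  equal n the exact two-sample KS statistic's lattice makes it visibly
  conservative), Fisher 2×2 with margins 2000, ANOVA 3×20 normal (where
  F is exactly calibrated). Exact small-sample paths are instead
  verified against enumeration oracles in the unit tests, where
  discreteness-driven conservatism is expected behavior.
- **Replicate agreement** — R² of run-2 on run-1 HFs over a full
  default-design simulation on a 4-kb genome.

These scales were chosen to give the comparisons statistical teeth (3
s.e. bands, ≥ 95% recovery criteria) while remaining desk-side
computations.

## Numerical and design notes

- Coordinates are 1-based inclusive throughout; position arithmetic
  wraps modulo the genome length. All writers state this in headers.
- Region overlap resolution: protein_coding > rRNA > tRNA > noncoding
  (a coding consequence dominates reporting); uncovered positions are
  implicitly noncoding; wrap-around intervals (start > end) are allowed.
- Zero-depth sites are skipped (HF undefined), not imputed.
- Degenerate inputs are explicit: an empty founder set requires
  `allow_empty=True`; founder variants with HF 0 are skipped by the
  shift (a loss cannot be normalized); zero-variance spectra yield NaN
  correlations; a degenerate contingency margin returns p = 1 with a
  warning; zero within-group variance leaves F undefined.
- r×c Fisher tables use a seeded Monte-Carlo estimate (Patefield
  sampling of fixed-margin tables, 10⁵ by default, +1 correction) since
  no exact r×c routine is available in the stack; 2×2 is exact.
- Per-cell fraction summaries (e.g. % de novo per cell) are unweighted
  means over cells; weighting by variant instead changes the estimand,
  so both the per-cell table and the raw classes are emitted.
- Known limitations: no indel or rearrangement calling, no haplogroup
  assignment, no NuMT handling (inputs are assumed pre-aligned allele
  counts), no signature deconvolution (correlation only), no bootstrap
  support on dendrograms.
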