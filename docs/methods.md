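# Methods

`psgscan` implements a genome-scale scan for positively selected genes
(PSGs): branch-site codon-model likelihood-ratio tests on designated
branches of a species phylogeny, the ortholog/isoform/alignment filtering
that such scans require upstream, fragment-consensus species-tree
estimation, and the downstream enrichment statistics. This note records
the models, the numerical choices, and what the synthetic validation does
and does not demonstrate.

## The branch-site model

Substitution between sense codons follows the Goldman–Yang
parameterization: for codons *i*, *j* differing at exactly one nucleotide,

```
q_ij = pi_j * kappa^[transition] * omega^[non-synonymous],
```

zero for multi-nucleotide changes, diagonal set so rows sum to zero.
`kappa` is the transition/transversion rate ratio, `omega = dN/dS`, and
`pi` the equilibrium codon frequencies (F3x4 by default: products of
per-codon-position nucleotide frequencies estimated from the alignment,
with F1x4 and uniform as options). Stop codons are excluded from the
state space (61 states under the standard code).

The branch-site alternative ("model A") assigns each site to one of four
classes, i.i.d. across sites:

| class | background omega | foreground omega | weight |
|-------|-----------------|------------------|--------|
| 0     | omega0 (<1)     | omega0           | p0 |
| 1     | 1               | 1                | p1 |
| 2a    | omega0          | omega2 (>=1)     | (1-p0-p1) p0/(p0+p1) |
| 2b    | 1               | omega2           | (1-p0-p1) p1/(p0+p1) |

Foreground branches are marked with the conventional `#1` newick suffix
or via the API (the edge above the MRCA of named taxa). The null model
fixes `omega2 = 1`; twice the log-likelihood difference is referred to a
chi-square with one degree of freedom, which is the convention this scan
uses (the 1/2:1/2 boundary mixture, which halves the tail, is available
behind a flag). Per-site likelihoods are computed by Felsenstein pruning
with per-node rescaling; gaps and ambiguous codons are missing data
(partial likelihood 1 over all states). Observed stop codons are an
error by default.

**Rate scaling.** Branch lengths are expected substitutions per codon
site under the *mixture-averaged background* rate: all class generators
are divided by `sum_k w_k * rate(omega_bg(k))`. Scaling conventions move
branch-length estimates but cancel in the LRT.

## Fitting

Internally the optimizer works with branch lengths in raw units of the
unnormalized generators, which makes the class-conditional site
likelihoods independent of the class weights. Each fit proceeds as:

1. **Warmup** (coordinate ascent): optimize `(p0, p1)` against cached
   class likelihoods (no pruning needed), then `(kappa, omega0, omega2)`
   plus a global branch scale by bounded quasi-Newton, then each branch
   length by a 1-D line search against analytic per-edge profiles
   obtained from one pass of outside-subtree ("up") partials.
2. **Polish**: joint L-BFGS-B over all parameters in transformed
   coordinates with a hybrid gradient — analytic for branch lengths
   (`dP/dt = Q P` through the eigendecomposition) and class weights
   (class responsibilities), forward differences in log space for
   `kappa` and the omegas, where a perturbed omega only recomputes the
   site classes whose kernels use it.

Bounds: `kappa in [0.05, 50]`, `omega0 in (1e-5, 1]`,
`omega2 in [1, 99]`, branch lengths `[1e-8, 30]` raw units. Multi-start
policy (`n_starts`, default 3): the first start is standard defaults (or
a warm start), the rest are seeded random probes given one warmup round;
the best basin gets the full polish. In `branch_site_lrt` the null model
is fitted first and the alternative is warm-started at the null optimum
with `omega2 = 2.5` and the class-2 mass floored at 10% — at
`p0 + p1 = 1` the likelihood is exactly flat in `omega2`, so warm
starts must not begin on that boundary. Convergence is declared by
L-BFGS-B (relative f-tolerance 1e-11, projected-gradient 1e-3);
non-convergence is flagged on the result, never raised.

Local optima are real in this model (the `omega2` and weight dimensions
interact); the warm start plus random probes found the same optima as
exhaustive restarting in our calibration runs. A fitted
`p0 + p1 = 1` with `omega2` at its starting value is the *no-class-2*
boundary solution, not an optimizer failure: some truly-selected
replicates genuinely carry no recoverable signal.

## Site classification

`site_posteriors` reports per-site class posteriors. `"neb"` (naive
empirical Bayes) conditions on the MLEs. `"beb"` integrates over a
uniform discrete prior: 10 points per dimension on the `(p0, p1)`
simplex, `omega0 in (0, 1)`, `omega2 in [1, 11]`, with `kappa` and
branch lengths fixed at their MLEs (grid size configurable). "Selected"
sites are those with `P(2a) + P(2b)` above a 0.5 call threshold
(configurable).

## Upstream: orthologs, isoforms, alignment, block filtering

- **Reciprocal best hits** against a reference species define ortholog
  pairs; the scorer is global protein alignment (BLOSUM62, affine gaps
  -11/-1), with percent identity over aligned positions as the
  similarity statistic. Identity was chosen over positive-scoring
  fraction; the scorer is pluggable. Ties break to the smallest gene ID.
- **Isoform selection**: per species the isoform most similar to the
  reference isoform wins; a species is dropped below 70% identity to the
  reference or 50% to any other retained species (dropping the member
  least similar to the reference, iteratively).
- **Codon-aware alignment**: center-star protein alignment around the
  reference, back-translated to codons, so all gaps are codon-sized.
  This replaces a full progressive aligner; it is exact for pairwise
  problems and adequate at desk scale, and externally produced
  alignments can be supplied instead. Internal stop codons reject the
  sequence with a reason.
- **Conserved-block filter** (Gblocks-style, codon granularity): a
  column is conserved if gap-free and at least `b2` sequences (default:
  all) share the majority amino acid. Gap columns are always removed;
  runs of more than `b3 = 8` contiguous non-conserved columns are
  removed; blocks are trimmed to conserved edges; surviving blocks
  shorter than `b4 = 30` codons are removed. Keeping short variable
  stretches (the `b3` rule) is essential: removing every variable column
  would delete precisely the substitution-bearing sites the scan looks
  for. The emulation is documented, not claimed bit-identical to the
  original tool; the load-bearing output is the removed-column map, in
  0-based half-open codon coordinates of the input alignment.

## Candidate filters and the edge-site adjustment

Criteria I–V (defaults as published): (I) at least one sister-branch
species present; (II) at least 4 species; (III) at least 60 columns,
66.67% of columns, and 60% of reference codons surviving the block
filter; (IV) `omega2 < 100`, `omega2 >= 0.85`, background omega summary
<= 1, where the summary is the class-weighted background mean
`(p0+p2a) omega0 + (p1+p2b)`; (V) at most 20% of sites called selected.
All criteria are evaluated independently and all failures reported.
Because `omega0 <= 1`, the background summary never exceeds 1; the
threshold remains configurable. A `manual` flag supports reproducible
hand-curation.

Called sites within two codon columns (inclusive; configurable) of any
removed block are discarded and the LRT is *re-run* on the alignment
with those columns excluded ("adjusted P"); the alternative reading —
prune the site list but keep the original P — is available as
`mode="report_only"`.

## Trees

The species tree is the strict-majority (> 50%) consensus of per-fragment
trees from the concatenated alignment (15-knt fragments; a trailing
remainder under 1 knt merges into the previous fragment). Fragment trees
are estimated by neighbor joining on TN93 ML distances followed by
nearest-neighbor-interchange hill climbing under HKY85 with ML branch
lengths and `kappa` (empirical base frequencies with a one-count floor),
deterministic given the input, with externally computed newick trees
accepted as an override. Consensus branch lengths are means over the
trees containing the bipartition; ties at exactly 50% are dropped.
Candidates found with the global tree are re-tested with a tree
estimated from their own alignment (guarding against incomplete lineage
sorting); confirmation means the gene-tree P also reaches alpha.

## Enrichment statistics

- **Fisher set enrichment**: one-sided hypergeometric tail with
  fold-enrichment `(overlap/|query|) / (|set|/|universe|)`; the full 2x2
  table is reported. P-values are deliberately not corrected for
  multiple testing (a Benjamini–Hochberg helper exists, off by default).
- **Expression trimming**: the background universe is restricted to the
  5–95% expression quantile band (linear interpolation) of a reference
  set before resampling.
- **Draw-and-sum null**: per round, a fixed-size draw without
  replacement from each stratum's universe; the statistic is the summed
  special-gene count. Only the four counts per stratum matter, so the
  stratum abstraction (sizes) is the core API with a list-based wrapper.
  Exact mode convolves the per-stratum hypergeometric PMFs; simulation
  mode is a seeded Monte-Carlo. The pipeline follows the published
  conservatism: draw counts are not reduced to the expression-trimmed
  subset of the query genes. The reported "95% quantile" uses the
  *lower* convention — the largest support value `x` with
  `P(X <= x) <= q` — which is the convention the published quantile
  corresponds to (the exact CDF is 0.9474 at 11 and 0.9740 at 12);
  the usual inverse CDF is available as `convention="upper"`.
- **Binomial direction test**: exact binomial for direction concordance
  at chance 1/4. The default is the upper tail `P(X >= k)`; the
  published concordance P-value corresponds to the two-sided exact
  convention (of R's `binom.test`), available as
  `alternative="two-sided"`.

## Synthetic data

The generator produces the three inputs the pipeline consumes, with
ground truth:

- **Codon alignments** under the branch-site mixture: site classes drawn
  i.i.d. from the class weights (matching the likelihood's assumption —
  no rate autocorrelation), root states from `pi`, evolution by exact
  matrix-exponential transition sampling per branch. Optional uniform
  codon-level gap injection exists for filter testing; there is no indel
  realism and no attempt to imitate real codon usage or GC content.
- **Transcript catalogs**: per-species multi-FASTA with one true
  ortholog per species and decoy isoforms steered by random codon
  mutation into a target protein-identity band (±2%).
- **Gene universes**: log-normal expression (log-mean 3, log-sd 1.5 — a
  strongly right-skewed positive scale typical of transcript abundances)
  with a designated special subset.

Fixed seeds reproduce outputs byte-identically.

Because synthetic divergence is i.i.d. across sites, alignments lack the
long conserved domains of real proteins; block-filter retention on
synthetic data is therefore *lower* than on real orthologs at the same
mean identity. Passing tests demonstrate the statistical machinery —
calibration, power, coordinate bookkeeping — not the field realism of
any particular alignment.

## Validation scale and study conditions

The calibration experiments run on a canonical 8-taxon balanced tree
(background edges 0.08–0.12, total length ≈ 1.8 expected substitutions
per codon site — a moderately deep radiation) whose foreground is a stem
branch of length 0.25:

- **Type-I error**: 120 null replicates (`omega2 = 1`), 300 codons; the
  rejection rate at alpha = 0.05 must not exceed
  `0.05 + 3 sqrt(0.05*0.95/120)`. The branch-site null is conservative
  relative to chi-square(1), so observed rates sit well below alpha.
- **Power/recovery**: 30 replicates with `omega2 = 4` and class-2 mass
  0.1, 500 codons; median fitted `omega2` above 1 and rejection rate at
  least 0.5 above the null rate.
- **Likelihood oracle**: pruning equals exhaustive enumeration over
  internal-node states on all tree shapes with up to two internal nodes
  (4 taxa), 20 random parameter draws, to 1e-8.
- **Tree recovery**: 20 six-taxon 20-knt replicates, at least 90%
  recovered with Robinson–Foulds distance 0.
- **Enrichment oracle**: Monte-Carlo tails agree with exact convolution
  within three Monte-Carlo standard errors at every support point.

Batch sizes are the package's validation scale, chosen to give stable
empirical rates while keeping the full suite practical to run routinely.

## Known limitations

- The center-star aligner is not a full progressive MSA; badly gapped
  multi-species families should be aligned externally and supplied.
- BEB fixes `kappa` and branch lengths at their MLEs (the cited
  method's own device); uncertainty in those parameters is ignored.
- The block-filter emulation approximates, not replicates, the original
  tool; retention statistics should be compared qualitatively only.
- The per-gene tree re-test uses the same NJ+NNI estimator as the
  species tree; with very short genes the gene tree is noisy and
  unconfirmed candidates should be interpreted as "fragile", not wrong.
- No frameshift handling: out-of-frame transcripts are rejected with a
  reason code rather than repaired.
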