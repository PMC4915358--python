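# Methods

## Reconciliation model

Gene trees are embedded into the rooted binary species tree by
duplication–loss parsimony.  The LCA mapping assigns every gene-tree node
`v` the species-tree lowest common ancestor `M(v)` of the species of its
descendant genes; leaves map to their own species.  An internal node is
labelled a **duplication** iff `M(v) = M(c)` for at least one child `c`
(a condition invariant under swapping children), otherwise a
**speciation**.  An event "on branch b" means `M(v)` is the node at the
lower end of b; branches are addressed throughout by the set of species
descending from that node, and the descendant species of an event are
exactly that set.  Losses on the edge `(v, c)` count skipped species-tree
edges: `d(M(v), M(c)) − 1` below a speciation and `d(M(v), M(c))` below a
duplication, where `d` is the edge count of the species-tree path.

This is the classical parsimony reconciliation: deterministic, exact under
its own model, and linear-time per gene tree after species-LCA
preprocessing (Euler tour + sparse-table range-minimum, O(1) per query).
It attributes all gene-tree/species-tree discordance to duplication and
loss; incomplete lineage sorting, transfer and gene-tree estimation error
are not modelled, so on discordant input trees the event set is the
parsimony explanation, not a statement about history.  Probabilistic
reconcilers that co-estimate gene trees can place events differently on
such inputs; downstream statistics here depend only on the (event, branch)
assignments.

Unrooted input trees can be rooted by `root_by_cost`, which scores every
edge of the unrooted topology by `w_dup·D + w_loss·L` (default weights
1, 1) using the same reconciliation and keeps the minimum.  Ties break on
fewer duplications, then on the lexicographically smallest sorted
leaf-label tuple of the clade below the root edge; the first element of
that tuple is the clade's smallest leaf label, and extending the
comparison to the whole tuple makes the choice fully deterministic even
when smallest labels coincide.  The winning clade becomes the left child.

## Retention criteria

A duplication is **retained** when two conditions hold:

1. *Evidence* — at least `min_evidence_species` (default 2) species retain
   a gene in **both** paralog clades.  A species witnesses a duplication
   only if it keeps both copies; under the default threshold every
   terminal-branch (species-specific) event therefore fails, which is the
   reading under which the evidence criterion and "nonterminal" coincide
   at the aggregate level.  Internal-branch events witnessed by a single
   species (e.g. one clade spans two species, the other survives in one)
   also fail under the default; the threshold is configurable for
   sensitivity analysis.
2. *Full retention* — every species descending from the event's branch has
   ≥ 1 gene in each paralog clade.  For a branch with ≥ 2 descendant
   species this implies criterion 1, so the filter chain
   `retained ⊆ criterion-1 ⊆ all` is monotone by construction.

Events mapping to the species-tree root are retained or rejected by the
same rules — "species that diverged after the duplication" is then the
entire species set — and are flagged in the outputs because rooting
artefacts concentrate there.

## Parallel duplication detection

Two focal branches are compared (they must be nonterminal and
non-nested).  At **orthogroup level**, `K` and `n` count orthogroups with
≥ 1 retained event on each branch and `k` their overlap; the expected
overlap is `nK/N` and the upper tail `P(X ≥ k)` of Hypergeometric(N, K, n)
is summed in log space (logsumexp over log-pmf terms), so p-values far
below double-precision underflow retain an exact log10.  The universe `N`
defaults to orthogroups containing ≥ 1 gene from ≥ 1 species of each focal
clade — families that could in principle show an event on both branches —
and can be switched to all orthogroups; the choice is recorded in the run
report, and with the published aggregate counts the two conventions differ
visibly (e.g. 225·381/13,773 ≈ 6.2 expected overlaps under the all-
orthogroups universe).

At **gene level**, two duplications in one orthogroup are parallel hits on
the *same* gene iff every internal node strictly between them on the
gene-tree path (their LCA included) is a speciation: the pre-duplication
copies are then orthologs.  If either node is an ancestor of the other the
pair is not parallel by convention.  Qualifying pairs are deduplicated per
ancestral gene lineage, identified by the gene-tree LCA of the pair, so
serial duplications within one orthologous lineage count once; an
orthogroup can still contribute several gene-level records through
distinct paralogous lineages (two parallel events in one family is the
glutaredoxin-like configuration).

## Expression statistics

Expression enters as per-species TPM tables with a sample sheet (species,
condition ∈ {BS, M, leaf stage}, replicate).

* **Cell preference.**  Per gene, Welch's t on log2(TPM+1) between BS and
  M replicates (≥ 2 each), BH-adjusted across all tested genes; a gene is
  called BS- (M-) preferential when adjusted p ≤ α (default 0.05) and the
  BS/M mean-TPM ratio is ≥ `min_fc` (default 2) in the called direction.
  Genes below 1 TPM mean in both conditions are not tested.  When both
  replicate groups have zero variance the t statistic is undefined; the
  guard reports p = 0 for unequal means and p = 1 for equal means, which
  makes noiseless simulations exactly recoverable.  The published analysis
  called differential expression from read counts in a negative-binomial
  framework; this package works at TPM level by design (read processing is
  out of scope) and accepts precomputed calls wherever a `calls` frame is
  consumed, so count-based calls can be substituted.
* **Cohort enrichment.**  The BS (M) proportion of a duplicate cohort is
  compared with the background proportion by an exact binomial test,
  two-sided by clipped doubling of the smaller tail
  (`p = min(1, 2·min(P(X≤k), P(X≥k)))`).  Degenerate backgrounds (0 or 1)
  cannot be doubled; the guard returns p = 1 when the observation matches
  the degenerate expectation and p = 0 otherwise.  The background defaults
  to all genes with a valid call in the same species.
* **Dominance concordance.**  For retained events on an ancestral branch
  and two descendant species: each paralog clade's representative in each
  species is the species' highest-TPM gene of that clade (mean TPM over
  the chosen condition; ties on the arg-max break by gene id).  An event
  is assessed only when the higher representative exceeds the inclusion
  threshold (default 10 TPM) in **both** species; the per-representative
  reading of the inclusion rule is used.  Exact representative ties are
  excluded rather than split (deterministic, and measure-zero under
  continuous noise).  Concordant means the same clade dominates in both
  species; the result is invariant under a consistent A/B relabelling.
* **Term enrichment.**  Hypergeometric upper tail per term over orthogroup
  sets, BH across tested terms, significance at adjusted p ≤ 0.05.
  Annotation rows outside the universe are dropped with a warning.  BH
  adjustment is delegated to statsmodels and verified in the test suite
  against the literal step-up formula.

## Synthetic data

The simulator is the package's source of ground truth, not a fixture
store.

* **Gene forests.**  One ancestral gene enters at the species-tree root;
  along each branch every extant copy independently duplicates at rate λ
  and dies at rate μ (exponential waiting times per unit branch length;
  unit lengths substituted when absent) and copies bifurcate at
  speciations.  Only surviving lineages are emitted, with unary nodes
  suppressed; the truth lists every duplication with surviving descendants
  of both copies, with its branch and clade gene sets.  With μ = 0 the LCA
  reconciliation provably recovers the truth exactly — the identifiability
  anchor of the test suite — while with μ > 0 inferred events can move
  below their true branch or vanish, so truth equality is only asserted
  loss-free.  Fully extinct families are resampled by default so the
  family count is exact.  Defaults: λ = 0.08 and μ = 0.04 per copy per
  unit length on the unit-length 7-taxon example tree, giving on the order
  of one duplication per family with moderate fractionation — desk-scale
  conditions under which all pipeline behaviours are exercised.
* **Planted parallels** are forced, not rejection-sampled, so truth counts
  are exact: a gene-level parallel duplicates the single ancestral lineage
  once on each focal branch (the connecting path is speciation-only by
  construction); an orthogroup-level parallel first duplicates on the
  branch ancestral to both focal branches and places one focal duplication
  in each copy, making the pair paralogous.  Planted trees are otherwise
  congruent with the species tree, hence fully retained.
* **Expression.**  Per-gene log-normal baselines (log2 mean = log2 of the
  TPM scale, default 20; between-gene sd 1.5).  A fraction f (default 0.2)
  of genes is BS-preferential with a 4-fold BS shift.  For truth events on
  the concordance branch (default: crown grasses) with representatives in
  both comparison species (default *Z. mays* / *O. sativa*), one clade is
  made dominant in species 1 and the same clade in species 2 with
  probability c (default 0.74); dominant/recessive whole-leaf means are
  100/20 TPM, both safely around the 10 TPM inclusion rule.  Replicate
  noise is log-normal with σ = 0.25 (log2 scale), 3 replicates per
  condition — the replication level of the motivating experiments.  Nested
  events competing for the same genes are planted first-come, remainder
  skipped and absent from the dominance truth.

What the simulator does *not* emulate: sequence evolution and gene-tree
estimation error (gene trees are exact), rate heterogeneity across
families, whole-genome-duplication block structure, count-level
(negative-binomial) expression noise, and correlated expression between
paralogs.  Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to gene-tree
error — on real data the reconciliation inherits whatever error the input
trees carry.

## Numerical and design choices

* Hypergeometric tails: log-space summation over the support; `k` at or
  below the lower support bound returns exactly 1, above the upper bound
  exactly 0.  Agreement with draw-by-draw enumeration is tested for all
  N ≤ 12.
* p-values are reported in linear and log10 scale, without truncation.
* TSV outputs are fully ordered (sort keys fixed) and floats printed at 6
  significant digits, so re-running a configuration is byte-identical.
* Newick dialect: labels containing metacharacters are single-quoted;
  internal-node labels are ignored on read except for the package's own
  reconciliation annotations; parsing is delegated to dendropy, with
  duplicate-leaf and empty-input checks on top.
* Polytomies are rejected by default because silent resolution changes
  duplication counts; an explicit policy resolves them deterministically
  left-to-right and flags the affected orthogroups.
* Species assignment is always by explicit map file — no identifier-prefix
  guessing.
* The seven-taxon example tree names the six monocots of the motivating
  study plus a placeholder `Outgroup` taxon standing in for the seventh
  sampled genome, so that the crown-grass branch is internal.
* Problem sizes in the test and acceptance runs (forests of tens to
  hundreds of families, hundreds of simulation replicates, 5,000-gene
  expression panels, 1,210-event concordance cohorts) were chosen as
  desk-scale stand-ins that still pin every statistic to its planted value
  within binomial error.

## Known limitations

* Parsimony reconciliation is biased toward fewer events on discordant
  trees; no confidence measure accompanies event placements.
* The overlap test conditions on per-branch orthogroup counts; it does not
  model heterogeneous duplicability across families, which inflates
  overlap in real data (a caveat for interpretation, not for the test's
  calibration under its own null).
* `root_by_cost` enumerates all rootings (O(n) reconciliations per tree);
  fine for forests of desk-scale trees, not optimised for very large gene
  families.
* The CLI accepts exactly one focal branch pair per run; joint tests over
  more than two origins are out of scope.
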