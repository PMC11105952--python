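# Methods

## Identifier mapping and orthology

Gene identifiers live in four namespaces: NCBI (Entrez) IDs, Ensembl gene
IDs, ZFIN IDs, and official gene symbols. Conversion is an exact string
match after whitespace trimming; symbol matching is case-sensitive by
default (zebrafish symbols are conventionally lowercase — `sox2`, not
`SOX2` — and silent case-folding across organisms can create false merges)
with an opt-in `fold_case` flag. One-to-many relations emit every target
rather than picking one; downstream set operations deduplicate. Unmapped
inputs are never silently dropped: every conversion returns them alongside
the mapped pairs, so the analysis universe never shrinks invisibly.

Orthology between zebrafish and human is stored as unique gene pairs and is
many-to-many in both directions. This is biology, not sloppiness: the
teleost whole-genome duplication left many human genes with two zebrafish
co-orthologs, and conversely. `to_human` / `to_zebrafish` therefore expand
each input to *all* of its orthologs. Mapping and orthology tables are read
from local TSV snapshots only; no network access, so results are
reproducible against a pinned snapshot.

An open question in table semantics — what to do when one source ID maps to
conflicting targets from different snapshot vintages — is resolved by
emitting all targets and reporting the one-to-many count, the only choice
that loses no information.

## Gene-set collections

Collections are GMT files (one set per line: id, description, members) with
optional `#key=value` header lines declaring the member namespace and
organism. Within-set order is never meaningful; serialization sorts members
lexicographically so outputs are byte-stable. Source databases (KEGG
pathway/disease, GO BP/MF/CC) are inferred from the id shape (`dre04010`,
`H00123`, `GO:0008150`) unless a header overrides them.

**Orthology projection** replaces each human set's members with the union
of their zebrafish orthologs. Sets retaining fewer than `min_size` genes
(default 5, configurable) are dropped and reported: a two-gene projected
set makes the Fisher table degenerate and the logistic fit unstable, so
testing it would produce noise, not biology.

**Counterpart identity and merging.** Two organisms' versions of a KEGG
pathway share a map number (`dre04010` / `hsa04010` → `04010`); GO ids are
organism-agnostic; KEGG disease ids are human-only and never have a
zebrafish counterpart. Matching is by id only — member-overlap matching
would be a different (and fuzzier) method. The `novel_only` merge keeps all
zebrafish sets and adds exactly those projected human sets whose key
matches no zebrafish set, treating zebrafish annotation as ground truth.
`all` keeps both versions, disambiguated by annotation organism. GO
annotation sets are taken as given in the input file; no propagation up the
ontology graph is performed (that is a property of how the input collection
was built, not of the enrichment step).

## Enrichment statistics

The DE table (`gene`, `pvalue`, `log2fc`) defines the universe; duplicate
genes collapse to their minimum p-value (conservative toward enrichment,
and the collapse count is reported), and p-values are clamped into
(0, 1] with zeros set to 1e-300 so −log p stays finite.

**Fisher.** Significance means raw DE p below a configurable threshold
(default 0.05), intersected with the fold-change sign for directional
tests; genes with log2fc exactly 0 count as neither up nor down. The
hypergeometric point probability is computed in log space (gammaln) and the
one-sided tail sums the point probabilities over the feasible range of the
table at fixed margins. The tails satisfy
P_over + P_under = 1 + point probability, which the test suite checks on
random tables, and both tails agree with exact big-integer enumeration to
better than 1e-12 relative error on an exhaustive small-N margins grid.
The reported effect is the sample odds ratio ad/bc (infinite when b·c = 0
with a·d > 0).

**Logistic.** Membership is regressed on x = −log p by Newton–Raphson IRLS
with step-halving; convergence when the relative log-likelihood change
drops below 1e-8 (100 iterations cap), standard errors from the observed
information at the optimum (identical to expected information for the
canonical logit link). Natural log is used for x; the Wald p-value is
invariant under any positive rescaling or shift of x (a tested property),
so the base is a pure convention. Complete separation — the two classes'
x-ranges failing to overlap — is detected up front and returned as a
non-converged fit with a diagnostic rather than divergent estimates; in a
collection run such sets are skipped with a logged notice. This situation
is routine for the *wrong*-direction test of a strongly regulated set,
where most member evidence has been masked to zero.

Directional logistic tests mask evidence rather than subset genes: for the
up test, x_i = −log p_i when log2fc_i > 0 and 0 otherwise (symmetrically
for down). Zeroing rather than removing keeps the universe, and hence the
membership baseline, identical across directions; a wrong-sign gene
contributes "no evidence" rather than vanishing.

**Collection runs** test every set (or a requested subset), skip degenerate
sets (no member in the universe, or the whole universe), adjust p-values
across exactly the tested sets (Benjamini–Hochberg by default; Bonferroni
and none available — raw-p reporting reproduces uncorrected "p < .05"
conventions), and sort by p-value with ties broken by set id for
byte-stable output. The `pct_sig_genes` column, 100·a/(a+c), feeds the dot
plot's size channel.

## Plots

The data-extraction layer is pure and tested directly: top-n selection per
direction (sort by p, tie-break by id), group counts for bar charts, and
volcano coordinates (x = log odds ratio for Fisher or β for logistic,
y = −log10 p). Rendering is matplotlib with a diverging color scale
anchored at zero so up- and downregulation are visually symmetric;
orthology-derived sets get a highlighted marker edge. Figures are
smoke-tested for non-empty, format-valid output only — aesthetics are not a
contract.

## Synthetic data and calibration

The generator's defaults describe the reference study conditions: a
2,000-gene zebrafish universe, 2,000 human genes, 200 gene sets of 20–100
members (typical KEGG pathway sizes scaled to the universe), 35% of human
genes without a zebrafish ortholog — matching the ~65% orthology coverage
of the human protein-coding genome — and 30% with two co-orthologs. One
integer seed drives independent substreams per artifact (mapping,
orthology, collection, and per-replicate DE tables), so changing the number
of sets never perturbs gene-level draws, and all outputs are
byte-reproducible given the seed.

Null DE p-values are Uniform(0, 1) with fair-coin fold-change signs.
Planted sets draw member p-values from Beta(a, 1) — the canonical
one-parameter stochastically-small family, with a ∈ (0, 1] an interpretable
effect strength (a = 1 is the null) — and match the planted direction's
sign with probability 0.9, reflecting that real pathway perturbations are
predominantly but not perfectly coherent in sign. Fold-change magnitudes
are half-normal; only the sign carries meaning for the tests. Overlapping
planted sets resolve by later plantings overriding earlier ones (logged).

`calibration_run` estimates the type-I error as the mean over replicates of
the per-replicate fraction of non-planted sets rejected at raw p < α, with
the Monte-Carlo standard error taken across replicates — sets within a
replicate share a universe and are correlated, so the replicate is the
correct Monte-Carlo unit. Power runs use 50 sets of fixed size 30 so the
effect parameter is the only dial varying across planted sets; a set counts
as detected when its smaller directional raw p-value clears α, with the
direction read off the smaller side.

Measured behavior under the reference null conditions (500 replicates):
the logistic/Wald test rejects at ~0.047–0.048 and Fisher at ~0.031 against
a nominal 0.05. Both shortfalls are properties of the tests, not the
implementation: Fisher's exact test is conservative on discrete tables
(with ~100 significant genes in 2,000 and pathway-sized sets, the attained
level is far below nominal), and the Wald test's χ² approximation converges
slowly under a skewed covariate (x is exponential under the null) — an
independent likelihood-ratio cross-check attains ~0.046 under the same
conditions. Power on planted signal is monotone in effect strength and
direction recovery exceeds 95% for both methods.

**What the simulation does not emulate:** correlated gene-level statistics
(co-expression makes real DE p-values dependent within pathways, typically
inflating enrichment false positives relative to this independent-gene
null), negative-binomial count noise and the DE-testing step itself,
realistic annotation bias, or symbol aliasing/history. Passing calibration
here therefore validates the statistical machinery under its own model
assumptions, not the field-level operating characteristics on any
particular RNA-seq dataset.

## Problem sizes

The test suite and the acceptance script run the calibrations at 500
replicates (type-I) and 100 replicates (power), the Fisher exactness check
on an exhaustive margins grid for N ≤ 26 plus stride-sampled margins to
N = 60 (several tens of thousands of tables), and the coverage computation
at the full 20,644-gene human census scale. These sizes give Monte-Carlo
standard errors below a milli-unit on rejection rates while keeping a full
run in the low minutes on one core.
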