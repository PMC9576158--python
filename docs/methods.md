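# Methods

## Genotype model and filtering

Genotypes are diploid biallelic dosages of the alternate allele: 0, 1, 2,
with a dedicated missing sentinel (never 0, so homozygous-reference and
no-call are unambiguous). Multi-allelic and non-SNP VCF records are skipped
and counted; VCF half-calls and phased genotypes are accepted, but any
genotype containing a missing allele is treated as fully missing.
Heterozygotes are retained as data throughout — the package targets
outcrossing wild material where observed heterozygosity is informative —
and no pseudo-homozygote collapsing is performed.

"Integrity" is read as the per-locus call rate (fraction of accessions with
a non-missing genotype). The standard filter keeps loci with MAF ≥ 0.01 and
call rate ≥ 0.5, both thresholds inclusive; MAF is computed on non-missing
calls only, and filtering is joint across all accessions (not per batch).
The filter never alters surviving call values and is idempotent.

## Diversity statistics

All statistics are closed-form functions of the per-locus alternate-allele
frequency `p` (`q = 1 − p`) and per-locus called sample size `n`:

| statistic | formula | default / range |
|---|---|---|
| He (Nei gene diversity, biased) | `1 − p² − q²` | [0, 0.5] |
| Nei (unbiased gene diversity) | `(2n/(2n−1)) · He` | n = per-locus called count |
| Ne (effective allele number) | `1/(p² + q²)` | [1, 2] |
| PIC | `1 − (p²+q²) − 2p²q²` | [0, 0.375] |
| I (Shannon–Wiener) | `−p ln p − q ln q` | [0, ln 2]; natural log |
| Ho | heterozygote fraction among called | [0, 1] |

The unbiased correction uses the per-locus called count, so missingness is
handled locus by locus. PIC ≤ He always, with equality only at fixed loci.

**Locus-inclusion policy.** Per-population report rows average each
statistic over the loci *polymorphic within that population* (and `Np`
counts them); this is the convention of per-region diversity tables, where
fixed loci would otherwise dilute every mean, and it is why a per-region
mean MAF (~0.15–0.23) sits far above the whole-panel mean MAF (~0.13).
The whole-collection and core-versus-total reports instead use the
*all-loci* policy, so that the core's values are commensurable with the
total's over an identical locus set. Both policies are exposed
(`policy="polymorphic" | "all"`, CLI `--all-loci`), and each report names
the policy it used. The summary table's mean row is the unweighted
arithmetic mean of the population rows, with `Np` rounded to the nearest
integer (half-up). Report values are rounded half-up to 4 decimals
(2 decimals for retention percentages).

## Distances and trees

*Modified Rogers* uses pairwise-complete loci (each pair compared over the
loci called in both) rather than global complete-case deletion, which would
discard most loci at 50% integrity. Entries are clipped to [0, 1]; a pair
sharing no called locus is an error naming the pair. On complete data MR is
a metric (checked by exhaustive triangle-inequality tests).

*Nei (1972) distance* between populations is `−ln` of the normalised gene
identity over each pair's jointly defined loci. A pair with zero identity
would be at infinite distance; it is capped at a configurable finite value
(default 10) so neighbour joining stays well defined.

*Neighbour joining* re-implements the Saitou–Nei Q-criterion with two
determinism rules: exact Q ties are broken by the lexicographically
smallest sorted pair of node labels, where an internal node carries the
smallest leaf label of its clade; and a negative branch length is clamped
to zero with the deficit moved to its sister branch. The Q-matrix is formed
with a commutative outer sum so it is exactly symmetric in floating point
(otherwise exact ties could fall only in the lower triangle). The
implementation is O(n³) with an in-place compacted distance matrix, so the
~1,000-leaf accession tree builds in seconds. On additive matrices path
lengths reproduce the input exactly (1e−9), verified also against
scikit-bio's independent implementation. `cut_tree` clusters leaves by
removing internal edges longer than a threshold — the programmatic
counterpart of reading a dendrogram at a fixed tree scale.

*PCA* centres each locus, imputes missing calls by the locus mean, and
takes the SVD; component signs are fixed by making each component's
largest-magnitude loading positive. Variance fractions are the squared
singular values over the total variance.

## Core selection

The search honours *population priority*: one seed per population — the
member with the greatest mean modified Rogers distance to its own
population's other members, i.e. the most divergent representative, with
lexicographic tie-break — is fixed in the core, guaranteeing every
population at least one member.

The objective is the convex combination
`score(S) = w_mr · MR(S) + w_sh · SH(S)` with default weights 0.7 / 0.3,
read as weights of a weighted-index multi-objective (the usual way such
weight pairs are used by core-selection software), not as parameters of
the measures themselves. `MR(S)` is the mean pairwise (entry-to-entry)
modified Rogers distance within the subset; an entry-to-nearest-entry
variant is available (`mean_nearest_mr`) for users who prefer that
criterion. `SH(S)` pools allele frequencies across loci — each allele's
share is its within-locus frequency divided by the number of defined loci,
so shares sum to one — and normalises the entropy by `ln(2L)` to [0, 1].
Internally the optimizer uses the identity
`SH = (ln L + mean_l H_l)/ln(2L)` (per-locus entropies `H_l`), which makes
candidate-move evaluation a vectorised per-locus update.

The engine is deterministic steepest-ascent swap hill-climbing with
restarts: restart 1 fills the non-seed slots greedily by objective gain,
later restarts fill them uniformly at random from the seeded RNG; each
start is improved by best-swap moves (only non-seed members may leave)
until no swap improves (bounded by `max_sweeps`, default 200 in the
library, 25 in the pipeline where panels are large); the search stops
after `max_no_improve` consecutive restarts without a better incumbent.
The accepted-move trace is monotone and the final objective never falls
below the greedy start. A simple deterministic hill-climber was chosen
over replica-exchange metaheuristics because it is desk-scale verifiable —
the test suite checks it attains the exhaustive optimum over all C(10,4)
seeded subsets — and the function interface leaves room for other engines.

The default core size is the smallest k whose *greedy coverage ranking*
(rank 1 = most distinct alleles, later ranks = maximal marginal new-allele
gain, ties by id) reaches 99.9% allele coverage, floored at the number of
populations. Note the size rule uses the greedy curve; the optimised core
maximises the weighted objective, not coverage, so its own coverage can
sit slightly below the greedy curve at the same k. The gradual-clustering
reading of per-group screening is available as the seed-constrained global
optimisation described above; per-group proportional allocation can be
emulated by running the optimiser per population subset.

## Evaluation

The retention report recomputes the nine statistics over all loci for the
full collection and the core and prints `100 · core/total` per statistic
(2 decimals, half-up) plus the core-size percentage. MAF is recomputed
within the core, so its retention can exceed 100 (rare alleles become
relatively commoner in a diversity-enriched subset). `Na` retention is 100
exactly when both sets segregate at every locus. Origin counts mirror the
per-region table with a summed totals row; the PCA overlay re-uses the
full-collection scores unchanged and adds an in-core flag.

## Synthetic data

The simulator is a Balding–Nichols island model: ancestral alternate
frequency per locus from Beta(a, b) truncated to [0.01, 0.5]; per-deme
frequency from `Beta(p(1−F)/F, (1−p)(1−F)/F)`; genotypes Binomial(2,
deme frequency); uniform missingness. Defaults are the study-shaped
conditions: 14 demes of sizes 19, 48, 60, 38, 232, 128, 74, 90, 53, 120,
15, 22, 52, 47; 1,592 loci over 12 chromosomes with uneven weights
(heaviest 623, lightest 80, matching the panel's chromosome skew);
`F = 0.12`; Beta(1.4, 10.0), calibrated once so the post-filter mean MAF
lands near 0.128 while ≥ 95% of loci survive the standard filter;
missing rate 0.1, a realistic no-call level for a multiplexed amplicon
panel comfortably above the 50% integrity floor. Chromosome positions are
sorted distinct uniform draws. The RNG is numpy's PCG64
(`default_rng(seed)`) as part of the public contract: same seed, same
matrix, bit for bit.

What the simulator does *not* emulate: linkage disequilibrium (no analysis
here uses it), rare locally-private alleles and other fine-scale site
frequency spectrum features, admixture gradients between demes, and
genotyping error. Consequences worth knowing: allele coverage saturates
far faster than in real panels (greedy coverage reaches 99.9% within a few
dozen accessions, versus hundreds in a survey rich in rare alleles), so
pipeline-default core sizes on synthetic data are small; and model-based
ancestry structure is smoother than real admixed material. Passing tests
therefore certify the statistics, distances, search behaviour and
plumbing — not the empirical core-size economics of any real collection.

Recovery checks hold by construction and are tested: per-deme expected
heterozygosity has mean `(1−F) · He_ancestral`; the origin-constrained
regression of among-deme frequency variance on `p(1−p)` recovers `F`
within 15% at 1,592 loci.

## Pipeline and determinism

`run_all` executes load → filter → diversity → distance → tree → PCA →
core → evaluation into a fixed artifact layout, logging versions, per-stage
record counts and timings; any stage failure aborts with a stage-named
error and keeps earlier artifacts. The population NJ tree is skipped (with
a log line) when fewer than three populations are attached. All
non-log artifacts are byte-reproducible for a fixed config. Scaled problem
sizes used by the test suite — 10×20 panels for statistical oracles,
six-deme 120-accession replicates for the 30%-sampling retention
properties, a single full-scale 998×1,592 run — were chosen as the
smallest sizes at which each property is informative.

## Known limitations

* Biallelic diploid only; no imputation; multi-allelic records are skipped,
  not decomposed.
* Nei distances between populations with very few members are noisy; no
  small-sample correction beyond the per-locus unbiased gene diversity.
* The hill-climb optimiser guarantees a local optimum per restart, not the
  global one, outside exhaustively checkable sizes.
* No bootstrap support on trees; no model-based ancestry estimation
  (cluster labels for plots come from tree cuts or k-means on PCA scores).
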