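# Methods notes

## The test in outline

A candidate evolutionary model is a fully resolved unrooted tree with fixed
branch lengths plus a substitution model with fixed numerical parameters.
Its fit to an observed gap-free DNA alignment is measured against `q`
parametric replicates simulated under the candidate:

1. **Pair counts.** Each alignment is reduced to the 10 counts of unordered
   pairwise aligned character states, totalling `s = k·n·(n−1)` (ordered
   sequence pairs, so each unordered pair counts twice). This keeps the
   downstream `2s`/`4s` factors exact.
2. **Substitution fit.** `GGg = 4s·[(t2+t3)/2 − t4]` over those counts,
   algebraically `4s` times the Jensen–Shannon divergence (natural log)
   between observed and mean-replicate frequencies. The variance term
   `GGp = 2s·[mean(t1) − t2]` and the sum `GG` are computed on request; the
   default statistic is `GGg` alone. `A` is the mean `GGg` over candidates
   sharing a substitution scheme (`w` = number of candidate trees).
3. **Tree fit.** Per alignment, a scoring matrix `m` (match frequencies;
   mismatch frequencies divided by the P-factor) and one `D` value per
   node-specific taxon subset; `B = 1 − tanh(mean atanh r_s)` over the
   per-replicate Spearman correlations of D-profiles.
4. **Combined.** `T = A·B`, ranked ascending; `MS(preferred, competitor)` is
   the percentage of observed replicates with strictly lower preferred `T`
   (ties count against the preferred model).

## Assumptions and applicability

- Alignments are gap-free and strictly over {A, C, G, T}; anything else is
  rejected at parse time (case-insensitive; U accepted as T with a warning).
  The statistics are undefined for gaps/ambiguities, so data preparation is
  the analyst's responsibility.
- All 10 pair categories must occur in the observed alignment and at least
  once across each candidate's replicate distribution. This precondition is
  enforced by default; `ggg(..., check_applicability=False)` evaluates the
  statistic anyway under the `0·ln 0 := 0` limit convention, which is also
  used for individual replicates that lack a category (presence is required
  across the distribution, not per replicate — the only convention that
  makes the per-replicate `t1` terms computable).
- Candidate trees must be fully resolved and share one leaf set. Rooted
  Newick input is unrooted by suppressing the degree-2 root: splits, not
  rootings, define the subsets.
- When the observed data are themselves replicates of one of the candidates,
  the two replicate sets must come from disjoint random streams (the
  workflow draws separate sub-seeds).

## Node-specific subsets and D values

- Every internal branch contributes *both* side-subsets; the two sides are
  distinct subsets, never averaged. Duplicates across branches and trees are
  removed. The canonical subset key is the lexicographically sorted member
  list joined with `|`, and the global subset order is the sort of those
  keys — any fixed order works for rank correlation, but it must be (and
  is) identical across all alignments in a run.
- The scoring matrix for D computation is derived from the same alignment
  being profiled; observed data and each replicate use their own matrix.
  This is the only reading under which `V2_c > 0` is guaranteed (every
  co-occurring pair in a column contributed at least one count to that
  alignment's own frequencies), making the per-column ratio always finite.

## Numerical conventions

- Spearman correlations use average ranks for ties (ties are likely with
  small subset sets). `r_s` is clamped to ±0.999999999999999 before
  `atanh`; the upper clamp keeps the Fisher transform finite in
  self-comparisons, and the lower clamp is applied symmetrically to avoid
  `−∞`. If either profile is constant, `r_s` is undefined and set to 0 (no
  rank information), with a logged warning.
- `gg = ggg + ggp` is checked to 1e-9 relative in tests.
- `t2`/`t4` act on real-valued mean counts; the t function is applied
  unchanged.
- Rate matrices are normalised to one expected substitution per site at
  stationarity; `P(t) = exp(Qt)` is computed by eigendecomposition of the
  similarity-transformed symmetric form (exact for reversible `Q`), with
  tiny negative entries clipped and rows renormalised.
- Discrete gamma uses equal-probability categories represented by their
  category means (computed from regularised incomplete gamma functions),
  4 categories by default; with invariant sites, a site is invariant with
  probability `p_inv`, otherwise gamma with rates rescaled by
  `1/(1−p_inv)` so the mean rate stays 1. Free-rate heterogeneity takes an
  explicit (rate, weight) list constrained to mean rate 1.
- The simulator's draw order is fixed (root states, then per-site rate
  classes, then branch transitions in preorder) so a seed fully determines
  the output; replicate sets consume one generator sequentially.
- The pruning likelihood compresses site patterns and rescales partials
  per node, accumulating scale factors in log space per rate class; the
  rate mixture is combined per site by log-sum-exp.

## Goldman–Cox comparator

`δ = ln L(multinomial) − ln L(model)`. The multinomial likelihood is the
product over columns of observed site-pattern frequencies — the maximum
attainable for any iid-site model, so `δ ≥ 0` whenever the model likelihood
is evaluated on the same data. Following the comparison protocol, every
replicate's `δ` is computed under the model that *generated* it, so an
observed replicate's `δ` does not depend on the candidate it is compared
against; candidates differ only through the mean and spread of their own
`δ` distributions, summarised by `|Z| = |δ_obs − mean δ_SM| / sd` (sample
sd). Because `δ` is insensitive to which of two similar topologies
generated a replicate, the resulting MS for tree discrimination sits near
chance — the contrast the power study quantifies.

Model likelihoods here use *fixed* parameters (no per-replicate
re-optimisation); externally computed log-likelihoods can be supplied via
TSV (`replicate_id<TAB>loglik`) to mirror protocols that re-optimise, and
such `δ` values will differ systematically from the fixed-parameter ones.

## Synthetic data: what the generator emulates

The built-in simulator generates the study conditions end to end; no
external data are packaged. The default power study uses:

- **Trees.** Six taxa. Tree I `(((A:0.15,B:0.12):0.05,C:0.18):0.05,
  (D:0.14,E:0.11):0.06,F:0.20)`; Tree II regrafts A as sister to C,
  otherwise identical. Internal branches of 0.05–0.06 expected
  substitutions/site against terminal branches of 0.11–0.20 represent a
  moderately hard but resolvable rearrangement of short internal branches.
- **Substitution models.** GTR+G with AT-rich base frequencies
  (0.31, 0.19, 0.21, 0.29), transition-dominant exchangeabilities
  (AC 1.4, AG 4.0, AT 1.2, CG 1.1, CT 5.0, GT 1.0) and gamma shape
  α = 0.4 — values typical of organellar coding DNA; K80 with κ = 2.5 as
  the misspecified scheme.
- **Scale.** k = 10,000 columns, 20 observed replicates, q = 100 replicates
  per candidate, P-factor 10,000. These sizes keep a full study (simulation,
  scoring and the Goldman–Cox side) under a minute on one CPU while leaving
  the separation statistics stable across seeds; MS resolution at this scale
  is 5 percentage points (20 comparisons).

What the generator does *not* emulate: alignment error, indels and missing
data (the test requires gap-free input), compositional non-stationarity,
site-specific (e.g. CAT-like) profiles, and codon structure. Passing power
studies on these synthetics therefore demonstrate the statistics'
discriminatory behaviour under the stated models, not robustness to the
full messiness of real alignments.

## Design choices on genuinely open points

- `A` is computed per substitution scheme from the GGg values of all
  candidates sharing that scheme, then paired with each candidate's own
  `B` — mirroring the two-tree worked arithmetic.
- Per-competitor MS values are reported; a "worst over competitors" summary
  is left to the caller rather than guessing an aggregation.
- Ranking ties on mean `T` break by label order (stable sort).
- The CLI (`absfit` with subcommands simulate/counts/gg/dprofile/score/ms/
  gctest) is a thin layer over the library; every artifact-writing command
  emits a JSON manifest sufficient to regenerate it.

## Known limitations

- No ML optimisation: model parameters are inputs. Using non-optimal
  parameters degrades all candidates' fit and can distort comparisons;
  parameters should come from per-candidate optimisation done elsewhere.
- DNA only (d = 10); the category map is the single point of extension for
  other alphabets.
- The D statistic needs ≥ 2 taxa on both sides of every scored branch, so
  pendant splits carry no signal and n ≥ 4 is required.
- MS percentages quantise with the number of observed replicates; small
  studies should interpret 100% as "no observed exception", not certainty.
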