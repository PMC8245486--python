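# Methods

## Data model

The pipeline's substrate is a tidy replicate-level CFU table: one row per
{environment, host strain, fed community, species, replicate} with a
non-negative real count (CFU/worm in the host, CFU/mL in media). Counts are
stored as reals because a CFU/worm value is an average over a ground batch
of ~20 worms and need not be integer; full precision is kept throughout
(writers emit shortest-round-trip decimal strings, the reader parses with
round-trip float precision, so serialize∘deserialize is the identity on
values). Replicates are exchangeable labels; no pairing across conditions
is assumed. Validation enforces that every (condition, replicate) carries
one row per fed species, so downstream code indexes without defensive
checks.

Tables are CSV or TSV (chosen by extension), community lists joined by
`;`. Species metadata (label, native/non-native origin, collection,
taxonomy) is a separate CSV. Phylogenies are consumed as newick with branch
lengths; patristic distances are path sums over the tree (computed via
dendropy) and the tree-to-table species matching is exact string match
after an optional alias map — silent fuzzy matching hides errors.

## Composition statistics

Per-replicate fractional abundances are counts normalized by the replicate
total; zero-total replicates carry no compositional information and are
excluded from means but reported. A pair coexists when the rarer species'
mean fraction exceeds a threshold, default 0.02 — just above the ~1 %
detection limit that colony counting imposes (a species below
1/colonies-counted is often unobserved). Manual overrides (pair, category,
note) can replace the rule for specific pairs, e.g. when a sub-threshold
mean hides a species confirmed in several replicates; overrides propagate
into the assembly rule. Classification is monotone in the threshold.

Relative yields are computed on the natural-log scale,
log RY = ⟨log((N_co+1)/⟨N_mono+1⟩)⟩, by bootstrap resampling co-culture
and monoculture replicates jointly (default 10⁴ iterations); the +1
pseudocount keeps the statistic finite at zero counts and the log scale
makes the calculation symmetric in numerator/denominator choice. The
reported uncertainty is the standard deviation of the bootstrap
distribution, not a percentile interval. The headline contrast
(RY ≶ 1 ⇔ log RY ≶ 0) is base-invariant.

The non-interacting null for a pair assumes each species reaches its
monoculture population; its expectation is the mean of N_i/(N_i+N_j) over
all ordered combinations of monoculture replicates (a combination with
both counts zero contributes 0.5 — symmetric ignorance, unreachable on
realistic inputs). Its s.e.m. divides by the *least* monoculture replicate
count: the combinations are not independent samples, and the smaller
replicate pool bounds their information content. The measured-vs-null test
is Welch's two-sided t between the replicate pair fractions and the
combination fractions, with the same least-replicate effective n for the
null sample. This choice is load-bearing: using the raw combination count
as n makes the test sharply anticonservative (empirically ~0.11 rejection
under a true null at α = 0.05), while the least-replicate convention is
calibrated for balanced designs (~0.053, checked by simulation in the
acceptance suite). The convention is a documented, swappable argument of
`null_deviation_test`. Multiple testing uses Benjamini–Hochberg.

Competitive ability is the mean fraction across a species' co-cultures; its
uncertainty is propagated from the per-pair s.e.m.s as √(Σ sem²)/m.

## Competition network

The hierarchy score ranks species by competitive ability (ties broken by
larger monoculture mean, then species id) and averages the fraction of the
higher-ranked species over all ordered pairs: 1 for a strict pecking
order, 0.5 for none; under ability ranking it cannot fall below 0.5. The
cited literature defines this score in a supplement not available here, so
the implementation operationalizes the one-line description and validates
against its stated extremes; the score function is a pluggable argument so
an alternative variant can be swapped in.

The permutation null preserves the multiset of measured fractions exactly:
each permutation reassigns the fraction/complement values to random pair
slots with random orientation, then *re-derives that null matrix's own
ranking* before scoring — scoring nulls with the observed ranking would
inflate significance. p = (1 + #{null ≥ observed})/(1 + n_perm), default
n_perm = 10⁵ (the null loop is vectorized in batches; ties in null
abilities have probability zero for continuous fractions and are broken by
stable argsort order).

Intransitivity scans all C(n,3) trios. Strict mode: a beats b when b's
fraction is at or below the exclusion threshold; relaxed mode: when a's
fraction exceeds 0.5, with an exact 0.5 tie marking the trio indeterminate
rather than cyclic. Strict cycles are a subset of relaxed ones.

## Prediction and assembly rules

For a community of n species the normalized arithmetic-mean predictor
averages each member's pair fractions against the other members and
renormalizes. The unnormalized means always sum to n/2, so the trio case
reduces to multiplication by 2/3; the same renormalization generalizes to
any n (equivalently factor 2/n). At n = 2 the predictor returns the pair
fractions themselves.

The assembly rule removes species that cannot survive their constituent
pairs. Default variant (`excluded_in_all`): a species is dropped only when
it is excluded in *every* one of its within-community pairs — the variant
matching the trio-level description. The `excluded_by_any_survivor`
variant iteratively drops species excluded by any remaining member, one at
a time (most surviving excluders first, ties by community order) until a
fixed point; one-at-a-time removal matters because a species whose only
excluder was itself dropped is retained. Both variants are idempotent on
their own survivor sets. After dropping, pairs involving dropped species
are excluded from the means and the prediction is renormalized over
survivors (dropped species get fraction zero). Reports name the variant
used; the 8-species default is `excluded_in_all`.

Errors between compositions are either the Euclidean distance in the
simplex normalized by its maximum √2 (attained between vertices, for any
community size) or the L1 distance normalized by its maximum 2; both are
symmetric, in [0, 1], and zero iff equal. The replicate noise floor — the
mean distance between each replicate composition and the replicate mean —
contextualizes every prediction error: batch-to-batch variability is the
scale below which differences are meaningless. Bootstrap clouds around
predictions (default 400 resamples, at the replicate level of the
underlying data) hold the survivor set fixed at the point estimate so the
cloud reflects compositional uncertainty rather than rule flips.

## Comparative analyses

Cross-environment comparison applies the same Welch contract per pair
(replicate fractions in the two environments as the two samples), counts
category shifts among significant pairs, and correlates per-species
competitive abilities (Spearman and Pearson) across environments.
Host-strain comparison reports per-species monoculture ratios with
bootstrap CIs, pair-fraction correlations, and L1 distances between matched
multispecies compositions with per-strain noise floors; fractions are
invariant to global scaling of one strain's counts, so a uniform immune
suppression of loads leaves the composition comparison untouched.

Trait dissimilarities are |log10(v_i/v_j)| for positive traits (monoculture
population sizes; log10 with absolute value keeps the matrix symmetric) and
|v_i − v_j|/max(v_i, v_j) for abilities (scale-free: 0.8 vs 0.4 is as
different as 0.2 vs 0.1). The Mantel test correlates upper-triangle entries
(Spearman by default), permuting one matrix's labels jointly;
p = (1 + #{permuted ≥ observed})/(1 + n_perm), one-sided toward positive
association, default n_perm = 10⁴.

## Synthetic experiment generator

No generative model exists in the underlying experimental literature; the
generator is this package's own, targeting the observable layer the
analysis consumes rather than mechanism (no generalized Lotka–Volterra
dynamics, no spatial structure, no priority effects, no bistability — the
experiments feed one initial composition and cannot detect it either).

Ground truth: carrying capacities K drawn log-uniform over 2×10²–2×10⁴
CFU/worm (population sizes spanning two orders of magnitude); a latent
competitive score s per species with pair fractions
F[i][j] = logistic((s_i − s_j)/τ). Default τ = 0.4 yields roughly
three-quarters coexisting pairs at the 2 % threshold, and s is drawn with
correlation ρ = 0.8 to log K, reflecting the empirical pattern that good
monoculture colonizers tend to be good competitors; both values were fixed
from the reported study-level proportions before any test was written. A
`random_matrix` mode (uniform independent fractions) provides the
no-structure null for the hierarchy score, and a `supplied` mode takes F
directly. A separate media fraction matrix can model environment-dependent
outcomes; per-host carrying-capacity multipliers model uneven immune
suppression.

Observation model per replicate: the community's expected composition is
the assembly-rule-consistent normalized arithmetic mean of true pair
fractions (pairs use F directly — exclusion is a downstream
classification, not a generative rule); the expected total is the
composition-weighted mean of survivors' carrying capacities; replicate
totals are lognormal with coefficient of variation `cv_total` (default
0.3); observed counts are total × a multinomial colony sample of depth
`colonies_counted` (default 100), which yields mechanistically the
count-depth-dependent ~1 % detection limit. Higher-order interactions are
a single knob: for communities of ≥3 species the expectation is perturbed
by one Dirichlet draw with concentration expectation/ε, a fixed property of
the ground truth (seeded per community), so ε = 0 makes "pairwise predicts
trios" exactly true and larger ε progressively breaks it. All randomness
descends from one integer seed via hashed child streams, so adding or
reordering conditions never perturbs another condition's draws.

What the generator does *not* emulate: real worm-to-worm heterogeneity and
colonization bottlenecks, facilitation (relative yields above 1), timing
and priority effects, and any mechanistic coupling between total load and
composition. Passing tests therefore demonstrate correctness of the
statistics and the internal consistency of the pipeline on data with the
stated structure — not that real communities obey the pairwise-consistent
model.

## Study-scale experiments and problem sizes

Two packaged experiments support calibration claims. The type-I experiment
simulates no-interaction studies (pair fractions built from independent
extra monoculture draws; 5 species, 8 monoculture and 4 co-culture
replicates, 200 studies) and checks that the null-model rejection rate at
α = 0.05 is compatible with 0.05. The error-ordering experiment (50
studies, 6 species, all 20 trios, ε = 0, default noise) reproduces the
qualitative ordering: uninformed > monoculture null > pairwise ≥ pairwise
with rule, the last on the same scale as the noise floor. These sizes keep
the full suite and the acceptance script in the tens of seconds while
leaving Monte-Carlo error well below the effect sizes being checked.

## Numerical choices and degenerate inputs

Compositions renormalize after division so the sum-to-1 invariant holds to
1e−9 exactly; a single replicate yields s.e.m. "not available" (NaN) rather
than 0; an all-zero-total condition is an error naming the condition;
empty bootstrap inputs and n_boot < 2 are errors; permutation p-values use
+1 smoothing so they are never 0. Ranking ties are broken deterministically
(monoculture mean, then species id). The CLI echoes the fully resolved
configuration and seed into every report, and identical seeds reproduce
byte-identical outputs.

## Known limitations

The hierarchy score is the description-faithful default, not a verified
re-implementation of the supplementary formula it descends from. The Welch
null-model contract (which second sample, which effective n) is a
documented choice among defensible options; very unbalanced monoculture
replicate counts make it conservative. The 8-species "mean fraction
against other survivors" wording leaves ambiguous whether pairs with
dropped species are excluded from means (implemented) or merely
renormalized. Facilitation and host-strain-dependent interactions are
representable only through supplied fraction matrices, not generated.
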