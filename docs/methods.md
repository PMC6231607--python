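# Methods

## The inference problem

A roster of `n` photographed community members defines the population.  Each
of `m` sampled respondents (themselves roster members) is shown a uniform
random subset of `k` photos and produces one *report*: a three-way binning
(close / recognized / unknown), a clustering of the recognized members into
at most `B` mutually exclusive groups of "people close to each other", and a
binary opinion on each of `M` attributes for every recognized member.  A
respondent shown their own photo gives it no bin, cluster, or opinion.  Only
the *recognized* bin enters the sociometric analysis: close and unknown
placements contribute to neither pair tallies nor observer sets.

The package turns these reports into three artifacts: a signed perceived
network, a member × attribute perception matrix over {−1, 0, +1}, and a
balance partition of the signed network, each with explicit statistical
control against a calibrated null model.

## The null model and its calibration

The null ("blind") respondent recognizes every other member independently
with probability γ, clusters uniformly at random over the `B` bins, and
affirms attribute *a* with probability β_a.  The free parameters are
`n, m, k, B` (design constants) plus γ and the β vector, which are
moment-matched to the data: γ = Σᵢ d(sᵢ)/(mk) with d(sᵢ) the recognized-bin
size, and β_a the pooled affirmative fraction among recorded opinions.

For a *uniformly random* pair of distinct members, one null respondent
recognizes both and co-clusters them with probability

p = (1/B) Σ_r Σ_ℓ z_r · [C(r,ℓ)C(n−r,k−ℓ)/C(n,k)] · [C(ℓ,2)/C(n,2)],

where z_r is the Binomial(n−1, γ) recognition-degree mass and
ℓ ∈ [max(2, k+r−n), min(r,k)]; the split probability is q = (B−1)p.  A
subtlety worth recording: the factor C(ℓ,2)/C(n,2) is *not* the
recognition-and-display probability of a fixed non-self pair (that would be
γ²C(k,2)/C(n,2), larger by n/(n−2)); it is exact for a pair drawn uniformly
from all C(n,2) pairs when the respondent is also a population member, since
with probability 2/n the respondent *is* one of the pair and can then never
place both in the recognized bin.  The simulator therefore draws respondents
as a random subset of the roster, which makes the analytic and simulated
pair statistics agree without any correction factor.

All combinatorial terms are computed in log space (log-gamma) and combined
with log-sum-exp; C(393, 40)-scale coefficients never overflow.  Degenerate
rates (γ ∈ {0, 1}) collapse the outer sum to its single admissible term.

Across `m` reports the pair counts are X ~ Binomial(m, p) and
Y ~ Binomial(m, q).  The cutoffs are Δ⁺ = min{w : P[X < w] ≥ level} and
Δ⁻ = min{w : P[Y < w] ≥ level}, with the *strict* lower tail as stated; an
observed count is significant when it is ≥ the cutoff.  At the study
parameterization (n = 393, m = 172, k = 40, B = 5, γ = 0.7622, level 0.95)
this yields Δ⁺ = 2 and Δ⁻ = 3, with P[X ≤ 1] ≈ 98.2% and P[Y ≤ 2] ≈ 95.2%
(the corresponding tails at m = 170 are 98.27% and 95.36%).

### Type-I guarantees

By construction P[X ≥ Δ⁺] ≤ 1 − level and P[Y ≥ Δ⁻] ≤ 1 − level *per pair,
unconditionally*.  The per-sign false-ascription rate among the pairs that
were co-recognized at least once is larger by the factor
1/P(any co-recognition) (≈ 1/0.64 at study scale) and can legitimately
exceed 1 − level for the negative sign; validation therefore checks the
unconditional rates over all C(n,2) pairs, which is the guarantee the
threshold construction actually provides.

## Tie ascription

Pair evidence is tallied once per report from the clustered (recognized)
members only.  A pair is ascribed +1 when x_obs ≥ Δ⁺, −1 when y_obs ≥ Δ⁻.
A pair meeting both cutoffs is *contested*: the default policy ascribes no
edge but keeps the pair in a ledger; `positive_wins` / `negative_wins`
policies are available and logged, and the resulting edge counts bracket the
default.  The node universe is every member recognized by at least one
respondent, so evidenced-but-isolated members survive into exports.

Single-sign summary statistics (degree, diameter, distances, transitivity,
centralities) are computed on the unweighted simple graph of that sign with
isolated nodes dropped; disconnected graphs use the largest component for
diameter and component-wise averages for mean distance; betweenness is
unnormalized.  The positive/negative degree correlation is a plain Pearson
correlation over the union node set with missing-sign degrees as zero.

## Attribute ascription

For member *j* with observer set O_j (respondents who placed *j* in the
recognized bin), the affirmation count f is compared to its null expectation
β_a·|O_j|.  Above it, an exact right-tailed binomial test (P[Z ≥ f]); below
it, left-tailed; a tail ≤ 1 − level yields +1 or −1, anything else 0.  The
tests are exact (no normal approximation), so they remain valid and
conservative at |O_j| of a handful.  Under one-sided tests gated by the
direction of f − β|O|, "both tests significant" cannot occur; if a future
decision rule produced it, the implementation falls back to 0.  β is
estimated globally per attribute; an external β vector can be supplied for
sensitivity analysis.  Raising the level can only move decisions toward 0
(monotone conservativeness), which the property tests enforce.

## Balance partitioning

The balance score of a partition is R = α·N_c + (1−α)·P_c (within-class
negative edges, cross-class positive edges).  Defaults: α = 0.5, so the
negative "robust intransitive" ties carry equal weight with positive ties,
and a minimum class size of 3, the smallest sociologically meaningful group.

The optimizer is a relocation-method local search.  Each repetition starts
from a random feasible partition (shuffle, deal `min_size` nodes per class
round-robin, place the rest uniformly) and applies steepest-descent moves —
single-node relocations (blocked when they would shrink a class below
`min_size` or empty it) and exchanges of two nodes from different classes —
until no move strictly decreases R (tolerance 1e−9).  Move pricing is O(1)
per candidate via per-node class-degree matrices, with an exchange
correction for an edge joining the swapped pair; matrices are updated
incrementally after each move.  A first-improvement mode skips exchange
pricing while an improving relocation exists, which is faster on large
networks at the cost of a different descent path.  Every accepted move
decreases R by at least min(α, 1−α), so termination is guaranteed.

Within a trial the best R over all repetitions is kept, along with *every*
distinct optimal partition after canonical relabeling (classes renumbered by
first occurrence in node order); a trial is "unique" when exactly one
distinct optimum was found.  The K sweep records per-trial best R, solution
counts, and smallest class sizes; model selection recommends the K with the
smallest median R, ties broken by fewer non-unique (outlier) trials, then by
smaller K — reported as advisory, with all criteria exposed.

For instances of ≤ 14 nodes an exhaustive enumerator (vectorized over all
K^n assignments, filtered to exactly-K partitions meeting `min_size`)
provides the global optimum; the heuristic is validated against it on
hundreds of random signed graphs and is required never to report a lower R
than the enumeration (which would indicate a scoring bug).

Desk-scale defaults are 10 trials × 100 repetitions; study-scale runs
(30 × 1000) are available by flag.

## Association stage

Ascribed attribute status (−1/0/+1) is regressed on class membership with a
multinomial logit: class dummies against a reference class (default: the
largest), outcome 0 as the reference outcome.  Fitting is plain Newton ML
via statsmodels with an iteration cap; empty class × outcome cells are
reported as quasi-separation flags alongside the (unpenalized) estimates,
whose standard errors are then legitimately enormous.  On fully tabular
data the fit is saturated and reproduces the empirical cell proportions;
changing the reference class changes coefficients but not fitted
probabilities or AIC — both identities are under test.  No multiple-testing
correction is applied across attributes.

## Synthetic data

The null simulator follows the blind-respondent model exactly, with
respondents drawn as a random subset of the roster (see above) and
per-respondent random streams (`default_rng([seed, slot])`), so increasing
`m` extends the respondent list without reshuffling earlier reports, and
identical configurations are byte-identical on disk.

The planted simulator assigns members to `K_true ≤ B` communities and routes
a recognized member to the bin indexed by its community with probability φ,
else to a uniform other bin.  φ is solved from the quadratic
φ² + (1−φ)²/(B−1) = θ_in so that same-community pairs are co-clustered with
probability exactly θ_in; the implied cross-community rate is checked
against θ_out and the configuration is rejected if it exceeds it.  The zero
contrast case θ_in = θ_out falls back to uniform bins, which reproduces the
null pair statistics exactly.  Ground-truth attribute roles are drawn from
per-community prevalences and observed through true/false-positive opinion
rates; a `close_prob` places some recognized members in the close bin so the
recognized-only restriction of the tallies is exercised.  This is a
deliberately simple perception model — no degree heterogeneity, no
respondent-specific reliability, no geography — so recovery results certify
the inference machinery, not realism of human perception.

Validation conditions (also the sizes used by the default test run): the
Monte-Carlo oracle compares 1500 simulated report sets at n=9, m=9, k=5,
B=3, γ=0.6 against the analytic p, q and pmfs, using the spread of per-set
means as the standard error (report sets are independent; pairs within one
are not); heuristic-vs-oracle runs 200 random signed graphs of 8–12 nodes
with K ∈ {2,3}; planted recovery uses n = m = 120, k = 40, B = 5, four
communities of 30, θ_in = 0.9, θ_out = 0.1, γ = 0.75, role prevalence
0.8/0.1, opinion rates 0.85/0.05, close_prob 0.05, over 10 seeds; type-I
control uses five pure-null report sets at the full study parameterization.

## Known limitations and open choices

* The sample-size ambiguity in the source study (170 completed interviews
  vs a quoted m = 172) matters only in the third decimal of the tail
  confidences; the cutoffs are (2, 3) under both.  Calibration always takes
  `m` from the data at hand.
* The C(ℓ,2)/C(n,2) term means the null model speaks about a random pair
  including the respondent in the pair universe; for a specific non-self
  pair the per-respondent probability is slightly higher.  At n ≈ 400 the
  difference is ~0.5%.
* Whether respondents may leave recognized photos unclustered is a field
  reality the format supports only in lenient mode, where such members are
  dropped from pair tallies; strict mode (default) rejects them.
* Contested pairs (both cutoffs met) have no prescribed treatment in the
  source protocol; the default keeps them out of the network but visible in
  the ledger.
* The exhaustive enumerator is the only optimality certificate; for large
  networks the local search is a heuristic, and uniqueness claims are
  relative to the repetitions run, not proofs.
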