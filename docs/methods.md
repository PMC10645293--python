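# Methods

## Problem setting

A differential Hi-C experiment compares chromatin-loop contact counts
between two conditions. Counts at a loop pixel (10 kb bins by default)
arise from two sources: the distance-dependent polymer background shared
by all pixels at that genomic separation ("expected" counts `e`), and the
loop-specific enrichment ("looping" counts `o − e`, attributable to
loop-forming forces such as cohesin extrusion). Compartment- and
domain-level forces also contribute but are absorbed into `e`. The package
answers: given a design (depth per replicate, replicates, dispersion),
what fraction of loops can a two-condition comparison resolve?

## Fold-change compression

A biological fold change acts on the looping component only, so the
observed effect size is

    FC_observed = ((o − e) · FC_looping + e) / o .

`FC_observed` is affine in `FC_looping` with slope `(o − e)/o` (the
looping fraction), equals 1 at `FC_looping = 1`, and for gains is strictly
between 1 and `FC_looping` whenever `0 < e < o`. Compression is strongest
where the background dominates — short-range loops — because the looping
fraction rises with span. Loop losses (`FC_looping < 1`) use the same
formula; the observed ratio is then floored at `e/o` (total loss of
looping signal). The algebraic inverse
`FC_looping = (FC_observed·o − e)/(o − e)` is provided to express
observed-scale thresholds in looping units; it is undefined at `o = e`.

## Power model

Per-loop power uses the two-group z-approximation for overdispersed
counts (the form popularized for RNA-seq sample-size planning and equally
valid for any count-based assay): a single replicate's squared coefficient
of variation is `1/μ + φ` — shot noise plus biological dispersion — so
the log fold-change estimate from `n` replicates per group has variance
`2(1/μ + φ)/n` and

    power = Φ( √( n · ln²Δ / (2 · (1/μ + φ)) ) − z_{1−α/2} ) ,

clipped to [0, 1], symmetric in `Δ ↔ 1/Δ` (|ln Δ| is used; the test is
two-sided), with no continuity correction. `μ` is the loop's own observed
counts rescaled to the evaluated depth, `Δ` the compressed observed fold
change, and `α` the nominal 0.05 divided by the number of loops tested
(Bonferroni). At `Δ = 1` the expression reduces exactly to `α/2` — the
one-tail false-positive rate — which is also the formula's lower bound.

**Verified accuracy.** The closed form was checked against seeded
Monte-Carlo negative-binomial simulation (two-sided Wald test on log
group means, delta-method SE; empirical size 0.048 at α = 0.05) over
μ ∈ {20, 50, 200} × φ ∈ {0.001, 0.01, 0.04} × n ∈ {2, 4, 8} at Δ = 2.
Agreement is within ±0.05 except at the μ = 20, n = 2 corner, where the
closed form is **conservative** by up to ~0.09: it assigns both groups
the control group's shot noise `1/μ`, while the enriched group (mean 2μ)
actually has less. Planning decisions based on the formula therefore err
toward more sequencing at very low counts with two replicates. This is a
property of the adopted formula, not an implementation artifact, and is
deliberately left as-is for fidelity to standard practice.

Because the variance argument is `1/(cD) + φ/n` when a fixed total depth
per condition `D` is split over `n` replicates, power is non-decreasing
in `n` at fixed `D`: more replicates are never worse. `solve_min_counts`
inverts the formula by bisection (relative tolerance 1e-6) and signals
unattainable targets (dispersion floor `n ln²Δ / 2φ` too small) with
infinity.

## Depth grids

Grid sweeps rescale each loop's reference-depth counts linearly
(`count × target/reference`), the expectation of thinning the underlying
contact stream; physical re-thinning is available through the `subsample`
machinery for validation but the deterministic expectation keeps grids
instantaneous and bit-for-bit reproducible. The loop list is fixed across
the grid (loops are not re-called per depth), so the Bonferroni divisor
is constant. Per-loop `μ` uses the loop's own observed counts rather than
a distance-smoothed value; smoothing via the decay fit is opt-in.
Default axes: depths per replicate {50 M, 100 M, 250 M, 500 M, 750 M,
1 B, 2 B, 3 B, 4 B, 5 B} contacts, replicates 2–10, dispersions
{0.001, 0.01, 0.04}, 2-fold looping change, 0.8 threshold ("well-powered"
is strictly greater). Percent-well-powered curves are computed
continuously in depth rather than interpolated between a fixed depth
ladder.

## Contact-stream thinning

Subsampling keeps each contact line independently with probability
`target/parent` using a seeded PCG64 uniform stream, one draw per line,
chunked for throughput (chunking does not change the decision sequence).
Lines are opaque and order-preserving, memory is constant in file size.
The realized count is Binomial(N, p); at a kept count of 1e9 the relative
deviation is below 1e-4 with ~3σ confidence, which is why the realized
count and its deviation are reported rather than forced to the whole
number. Exact-to-target (hypergeometric) sampling was deliberately not
used: per-line Bernoulli is simpler, streaming, and the slack is
negligible at planning-relevant depths.

## Distance decay

Per-bin count quantiles (q10/q25/median/q75/q90, linear interpolation
between order statistics) summarize counts vs span at 10 kb resolution.
The decay `count = a·d^b` is fitted by OLS on `log count ~ log d` —
deterministic and closed-form, appropriate for its de-noising/visual
role — with log-space R² reported and an optional natural-scale nonlinear
refinement (`refine="nls"`) initialized from the OLS solution. Spans are
measured start-to-start on the sorted anchors (keeps binned spans on the
bin lattice); "shorter than 2 Mb" and "observed greater than expected"
filters are strict inequalities; chromosome names accept both `chr1` and
`1` dialects.

## Common dispersion

`φ` is estimated from a loops × replicates pilot matrix by maximizing the
**Cox–Reid adjusted profile likelihood** of a common negative-binomial
dispersion: per candidate `φ`, each loop's mean is profiled at its
offset-adjusted MLE (library sizes normalized to mean 1 as multiplicative
offsets; vectorized Newton), the likelihood is penalized by half the log
Fisher information of each profiled mean, and the scalar search runs on
`log φ` (bounded, tolerance 1e-8). The adjustment matters: the
unpenalized profile MLE is biased low by roughly `(n−1)/n`, i.e. ~25% at
4 replicates. Under-dispersed data return `φ = 0` (Poisson boundary);
all-zero rows are uninformative and dropped (counted); fewer than 20
informative loops triggers a warning. On simulated data the estimator
recovers `φ` ∈ [0.001, 0.1] within a few percent at 5,000 loops × 4
replicates, and it agrees with edgeR's `estimateDisp` common dispersion
(the same adjusted-likelihood idea) to ~0.1% on shared input.

## Synthetic data

The generator emulates a deeply sequenced human lymphoblastoid
(GM12878-like) loop call set so every module is testable offline:

* **Spans** — log-normal, median 300 kb, log-sd 0.75 (short-skewed),
  truncated to [20 kb, 2 Mb), floored to the 10 kb lattice.
* **Expected counts** — power-law decay `a·d^b` with `b = −1` and
  `a = 1.26e7`, calibrated so a 350 kb pixel carries ~36 expected counts
  at the full reference depth of 5,536,073,657 contacts.
* **Looping fraction** — rises linearly in log-span from 0.5 (20 kb) to
  0.8 (2 Mb); observed = expected / (1 − fraction) with 10% CV
  multiplicative log-normal noise (a fixture choice, separate from
  replicate-level dispersion), floored just above expected so every
  record passes the inclusion filters.
* **Replicate counts** — negative-binomial around depth-scaled observed
  means with the requested `φ` (Poisson at `φ = 0`); a second condition
  applies the compressed observed fold change.

All generation is deterministic per seed (PCG64). What passing tests on
this fixture do **not** show: real loop sets have anchor-level structure,
correlated counts between nearby loops, loop-calling noise, and higher
median counts than this conservative calibration — so absolute
percent-well-powered values on real data will differ (the depth at which
half the synthetic loops are well-powered lands near ~1e10 contacts per
condition here), while the qualitative structure (sigmoidal depth
response, short-loop advantage, replicate/dispersion trade-offs) is
faithful.

## Numerical choices and limitations

* Quantile rule: numpy's linear interpolation, fixed and documented.
* Power clipped into [0, 1] after evaluation; bisection via Brent.
* Ties at the power threshold: "well-powered" is strictly `> threshold`.
* Problem sizes used by the test suite (10,000-loop fixtures, 1e5
  Monte-Carlo draws per oracle cell, 2e8-record thinning runs; the
  acceptance script streams 2e9 decisions) were chosen so the full
  suite completes in a few minutes while keeping Monte-Carlo error well
  inside the asserted tolerances.
* The package plans power only: it is not a differential caller (no
  exact NB likelihood-ratio testing), does not build contact matrices or
  call loops, and its defaults encode human Hi-C at 10 kb resolution —
  enrichment-based protocols (HiChIP, ChIA-PET, capture) and other
  resolutions need their own calibration.
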