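# Methods

## Scope and data model

The package analyses *myth cascades*: for each of 27 WHO-Mythbuster myths,
the set of tweets whose text contains the myth's keyword phrase(s) together
with at least one generic pandemic keyword ("covid19", "covid-19",
"corona virus", "coronavirus", "2019-nCoV", "2019nCoV"). Matching is
case-insensitive substring containment on whitespace-normalised text,
approximating search-API semantics; a stricter token-boundary mode is
available. Multi-phrase myths carry an explicit AND/OR marker in the
catalog CSV: paired concepts ("Masks" + "CO2 intoxication") require both
phrases, alternative namings ("Bleach"/"Disinfectant") require either.
The operator is data, not code, because the printed source table does not
state it. A tweet may match several myths; all labels are kept, and a
single *primary* myth — the earliest match in catalog order — assigns the
tweet to one category so that per-category counts partition the corpus.

The observation window defaults to 1 January – 7 July 2020, inclusive,
with days binned in UTC. Distinct-user identity is the numeric user id.

## SIR diffusion model

Each category's cascade is modelled with the classic SIR system in
fractions of an effective population `n_eff`:

    dS/dt = -β S I,   dI/dt = β S I - γ I,   dR/dt = γ I

with β the per-day transmission rate, γ the per-day recovery rate. A user
is "infected" when they first post about the myth; the cumulative number
of distinct posting users is identified with `n_eff · (I + R)`. The basic
reproduction number is R0 = β/γ, and R0 > 1 (strictly) classifies the
myth as an infodemic — the threshold at which the disease-free equilibrium
(S=1, I=0, R=0) becomes unstable.

Integration is fixed-step 4th-order Runge–Kutta, default step dt = 0.1 day
(capped at 0.1), sampled at integer days; conservation S+I+R = 1 holds to
1e-8 by construction. When numba is importable the inner loop is
JIT-compiled (~50× faster); results are identical to the pure-Python path.

### Likelihood

Daily new distinct users y_t (t = 1..T−1) are treated as Poisson with rate
μ_t equal to the model's daily increment of `n_eff (I+R)`, floored at
1e-10 to keep the likelihood finite when the model predicts an inactive
day. The NLL is Σ_t [μ_t − y_t log μ_t + log y_t!]; the factorial term is
constant in the parameters but keeps values comparable across datasets.
The day-0 count seeds the initial condition and does not enter the sum.
A cascade must span ≥ 7 days and ≥ 10 total users to be fitted. Fitting
daily new tweets instead of new users is available as a flag.

### Optimization

Nelder–Mead over log-parameterized (β, γ[, n_eff][, i0]) with five
deterministic starts (four structured, the rest seeded jitter), each
polished by restarting the simplex at its own optimum; simplex tolerance
1e-8, penalty walls at β, γ outside [1e-4, 50]. `n_eff` is mapped through
a scaled sigmoid so it stays smoothly inside [U, 100·U], U being the
observed distinct-user total, or is pinned via `fix_n_eff`. A
`converged` flag records whether the winning start met the tolerance.

Two deliberate deviations from the obvious defaults:

1. **The initial infected count i0 is a free parameter** (initialised at
   the first day's count, bounded in [0.01, n_eff/10]). A stochastic
   cascade's takeoff is randomly delayed relative to the deterministic
   trajectory started from the observed day-0 count; with i0 pinned, that
   timing error is absorbed by spurious slow-recovery solutions with
   R0 ~ 8–20. Freeing i0 (equivalently, a time shift) removes the
   artefact: across chain-binomial replicates at (β, γ) = (0.4, 0.2) the
   fitted R0 distribution collapses from [1.2, 20] onto [2.11, 2.22].
   The pinned rule remains available (`i0_mode="first_day"`).

2. **R0 and n_eff are jointly near-unidentifiable from one completed
   cascade.** The likelihood surface has a flat ridge along which a larger
   pool with moderate R0 trades off against a pool equal to the observed
   participants with very large R0; the global optimum generically sits at
   the n_eff lower bound with R0 of order 10–40, regardless of the truth
   (profile-likelihood grids and a least-squares-on-cumulative variant
   show the same ridge). This is a structural property of completed
   epidemic curves, not an optimizer failure — and it plausibly explains
   the extreme printed R0 values in empirical infodemic studies where
   n_eff was fitted. Consequently: parameter-recovery experiments condition
   on the known generator population (`fix_n_eff=N`), and fitted R0 values
   obtained with free n_eff should be read as qualitative (supercritical /
   subcritical) rather than point estimates.

### Discretization bias

The synthetic generator is a chain-binomial: per day, each susceptible is
infected with probability 1 − exp(−β I/N) and each infectious user
recovers with probability 1 − exp(−γ). Its effective per-day recovery
probability is 1 − e^(−γ) (= 0.1813 at γ = 0.2), so a perfectly specified
continuous-time fit estimates γ_eff and hence R0 ≈ β/(1 − e^(−γ)) = 2.21
at nominal R0 = 2.0. The observed median fitted R0 over replicates
(~2.16) reflects this plus small finite-sample bias.

## Synthetic corpus generator

The generator exists to give the pipeline a ground truth. It emulates:
daily first-post cascades from the chain-binomial above (every newly
infected user posts exactly once on their infection day, so the cascade's
daily new-user series equals the true new-infection series, plus
Poisson(posting_rate = 0.3/day) tweets while infectious); texts built from
one myth's keyword phrases, one pandemic keyword and neutral filler words
(validated disjoint from all catalog phrases, so labeling recovers the
intended myth with certainty); log-normal engagement and user metadata
(retweets LN(0, 2), favorites LN(1, 2), followers LN(8, 2), followees
LN(6, 1.5), lifetime statuses LN(8, 2), floored to integers; 2% verified);
and per-tweet Dirichlet emotion vectors with concentration 20 around a
fear-dominant mean (anger .09, disgust .03, fear .55, joy .25, sadness
.04, surprise .04) chosen to mirror the fear/joy-dominated profile
reported for real myth corpora.

It does **not** emulate: follower-graph topology (mixing is homogeneous),
retweet chains or content duplication, bot behaviour, diurnal/weekly
posting rhythms, multi-myth texts, or any correlation between emotion and
myth content. Passing tests therefore demonstrate correctness of the
pipeline and estimator calibration under the stated stochastic model — not
that real Twitter cascades follow SIR dynamics.

Default study conditions used in tests and in the acceptance script:
noiseless recovery at (β, γ, n_eff, T) = (0.4, 0.2, 10 000, 120); 50
chain-binomial replicates at the same parameters with i0 = 10; generator
recovery on a ~50 000-tweet corpus (N = 12 000); the optimizer-vs-grid
check on ten random cascades against a 50×50 log-spaced (β, γ) grid; the
end-to-end determinism check on a down-scaled five-category corpus.

## Topics

Tokenization lowercases, strips URLs and @mentions, removes '#', splits on
non-alphanumerics and keeps tokens of length ≥ 2. English stop words
(scikit-learn's list) are removed by default (the displayed terms are
content words); disable with a flag. Stemming is a from-scratch
implementation of the original Porter (1980) suffix-stripping algorithm,
verified against the complete set of published rule-example pairs (100%)
and against an independently written re-implementation over a generated
suffix-rich vocabulary. Term tables rank the top k = 14 stems by token
occurrence (ties lexicographic), with the remaining mass as an "other"
bucket — 15 display rows. The stems of the six pandemic keywords are
always excluded so the tables show discussed topics rather than the search
terms. Tweet-level proportions assign each tweet to the highest-ranked
named stem it contains, else "other", so proportions partition and sum
to 1; an overlapping "any-containing" mode is available and documented as
non-partitioning.

## Engagement

User summaries deduplicate users within a category and report mean/std of
log(1 + x) — natural log by default, base configurable (a change of base
rescales by exactly the change-of-base constant) — for followers,
followees, lifetime statuses (the "engagement" proxy) and account age in
days at a fixed summary date. Verified status is reported as a count and
proportion, not on a log scale. Reaction summaries are raw-scale mean/std
of retweet and favorite counts per tweet. Distributions are exported as
log-spaced histograms and empirical CCDFs, with the p99/median ratio as a
tail-heaviness statistic and a Hill estimator of the Pareto tail index
over the top 1% of positive values.

## Emotions

Profiles are probability vectors over Ekman's six classes in the fixed
order (anger, disgust, fear, joy, sadness, surprise); that order also
breaks argmax ties for the *dominant* emotion of a tweet. Vectors whose
sum lies in [0.99, 1.01] (e.g. rounded published tables) are renormalised;
anything further off is rejected. Classification is an injection point:
either a CSV of precomputed per-tweet probabilities (the intended path for
outputs of an external trained model, which this package deliberately does
not bundle or re-train) or the packaged lexicon stub — a transparent,
deterministic keyword counter with Laplace smoothing and a uniform
fallback, adequate for exercising the aggregation machinery and nothing
more. Corpus summaries report per-class means, 5/25/50/75/95% quantiles
(violin-style), and dominant-emotion proportions (which always sum to 1).

## Numerical and edge-case conventions

- RK4 step 0.1 day; integrator rejects dt > 0.1 and non-finite inputs.
- Poisson rate floor 1e-10; all-zero cascades are an error ("no cascade").
- An absent category yields an all-zero cascade, not an error; empty
  category slices are errors for summaries that would divide by zero.
- Malformed JSONL lines are skipped with a warning; more than 10%
  malformed (configurable) is a hard error.
- Term-frequency ties break lexicographically; emotion argmax ties break
  by class order.
- All randomness flows from `numpy.random.default_rng(seed)`; identical
  config + seed reproduces corpora byte-for-byte.

## Known limitations

- SIR with constant rates cannot represent multi-wave or late-surge
  cascades; a late surge inflates fitted R0 (this is by design the signal
  the infodemic flag reacts to, but it makes point estimates fragile).
- R0 from free-n_eff fits of completed cascades is weakly identified (see
  above); confidence intervals are not provided.
- The keyword matcher has no negation, sarcasm or stance handling: a
  debunking tweet matches the myth it debunks.
- The lexicon emotion stub is a test scaffold, not an emotion model;
  substantive emotion conclusions require an external classifier.
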