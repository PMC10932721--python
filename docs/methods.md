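# Methods

## Scope and data model

`langgame` implements an instruction-level sentiment analysis of the
dictator game. The unit of observation is an *experimental condition*:
one set of instructions, one country, and the 1–7 sentiment scores a
scorer assigned to the three prominent actions (keep all / give half /
give all) as described *in the instruction's own words*. Scores are
stored at the two-decimal precision the elicitation protocol requests.
A condition may lack `s_half`: binary dictator variants offer no equal
split, and that absence is carried as a first-class missing value,
never imputed.

The bundled corpus (`packaged_fixture`) transcribes the published
sentiment table of 61 conditions across 12 studies, with the six
conditions of the Capraro & Vanzo study lacking `s_half`. Countries
come from the source articles' stated subject pools; for the
multi-site or ambiguous cases (Dreber et al., Kettner & Waichman,
Walkowitz) the primary site was used. Country is deliberately inert:
it feeds prompt construction only, so any residual uncertainty cannot
affect a number. The corpus bundles no behavioural outcomes because
the per-condition giving rates of the source articles are not part of
the published score table; outcomes are user-supplied or synthetic.

Recomputing the bundled corpus's descriptives gives means
2.601 / 5.234 / 5.353 and s.d. 0.627 / 0.930 / 1.000 for
`s_zero` / `s_half` / `s_all`. The first two means and s.d. agree with
the published descriptive table to its printed (truncated) precision;
the published `s_all` mean (5.369) and s.d. (1.010) do not recompute
from the published per-condition values — apparently an internal
inconsistency of the source table — and the package reports the
recomputed values without forcing agreement.

## The ΔS statistic

```
ΔS = S_half − S_zero                if S_all ≤ S_half
ΔS = (S_all + S_half)/2 − S_zero    if S_all > S_half
ΔS = S_all − S_zero                 if S_half is absent
```

The two-action rule (third line) is this package's extension, not part
of the published definition, which is silent on binary designs: with
only two prominent actions the prosocial sentiment is `S_all` and the
comparison degenerates to a two-action contrast. It is flagged by the
returned branch label so downstream users can filter it out.

ΔS depends only on score differences (translation invariant), is
non-increasing in `S_zero` and weakly non-decreasing in `S_half` and
`S_all`, and is continuous at the branch boundary `S_all = S_half`,
where both branches reduce to `S_half − S_zero`. The test suite checks
all of these, plus exact agreement with a brute-force evaluation of
the decision rules on the quarter-point grid of [1,7]³.

Case classification uses the same weak inequality as ΔS: ties between
`S_half` and `S_all` count as the two-action dilemma, and a selfish
score merely tied with the maximum does not make the selfish action
dominant. Ties therefore resolve towards the more prosocial label.

## Choice model

Utility is additive, `U(a) = π(a) + λ·s(a)`, with softmax choice at
temperature `T`. The published argument fixes only monotonicity in
payoff and sentiment; the additive form and the softmax link are the
minimal operationalization consistent with the three-case taxonomy,
and both `λ` and `T` are exposed rather than asserted.

Parameters:

- payoffs `(π_zero, π_half, π_all)`, default `(10, 5, 0)` currency
  units — a 10-unit endowment as in the canonical instruction example;
- `λ ≥ 0`, payoff units per sentiment point, default 1 (one sentiment
  point ≈ one tenth of the endowment);
- `T > 0`, choice-noise scale, default 1. `T → 0` approaches strict
  maximization; large `T` approaches uniform choice.

Dominance uses the mixed strict/weak rule: A is dominated by B when B
is strictly better on one coordinate (payoff or sentiment) and at
least as good on the other. With strictly ordered payoffs this
reproduces the taxonomy's claims exactly: the selfish-dominant case
dominates both prosocial actions, the two-action dilemma always
dominates give-all, and the three-way-tension case (with strict
sentiment ordering) dominates nothing. At sentiment ties a dominated
action can coexist with the three-way label; the tests assert the
implications that hold under the tie rules rather than a false
equivalence.

Simulated agents draw i.i.d. choices from the softmax distribution;
the prosocial rate is the share choosing give-half or give-all. Within
this model the central behavioural hypothesis holds: across random
sentiment triples at fixed payoffs and parameters, simulated prosocial
rates rank-correlate with ΔS at ρ ≈ 0.97 (600 triples, 500 agents
each).

## Elicitation protocol

Prompts follow the published template: the verbatim instruction text,
then "Now imagine that there is a population of 1000 people living in
[country]…", then one 1–7 question per action using the instruction's
own action phrases, requesting an exact two-decimal number. Variants:
`usa_population` substitutes the USA; `unspecified_size` omits the
population size; `single_chat` keeps one running conversation per
study instead of a fresh one per condition. Replies are parsed by
taking the *first* decimal literal (a deterministic tie-break; raw
replies are logged for audit) and range-checked to [1, 7].

The backend contract is synchronous text-in/text-out with `reset()`
for conversation boundaries and a configurable retry count (default
3). The bundled backend is a deterministic mock that hashes
(seed, transcript, prompt) to a two-decimal score; it exists to make
the pipeline runnable and testable offline and implies nothing about
any live scorer's behaviour. Reproducing the original scorer's numbers
is a non-goal — the bundled corpus, not re-elicitation, is the
reference dataset — so no live adapter ships with the package; users
can implement the `ScorerBackend` protocol against any API.

## Synthetic corpora

`generate_corpus` inverts the estimation pipeline. Per study
`k`: a random slope deviation `u_k ~ N(0, τ²)`; per condition:
sentiments drawn independently per action from normals truncated to
[1, 7] (location/scale defaults are the bundled corpus's per-action
moments), then

```
rate = alpha + (beta + u_k)·ΔS + N(0, σ²)
```

optionally observed as a binomial proportion of `n_participants`
draws. Heterogeneity enters as a random *slope* because the
meta-analysis pools slopes — τ² at the pooling stage estimates
exactly this quantity. Defaults (`k_studies=11`,
`conditions_per_study=5`, `alpha=0.3`, `beta=0.08`, `tau=0.02`,
`sigma=0.02`, exact rates) mirror the reference estimation setting:
eleven pooled studies of about five conditions with a slope of 0.08
prosocial-rate units per ΔS point.

Out-of-range latent rates are handled by redrawing the condition noise
(up to 100 retries), then clamping to the boundary and counting the
clamp in the returned ground truth; a configuration that forces every
draw out of range raises. Truncation of the sentiment normals means
per-action sample means track the *truncated*-normal means, which for
the `s_all` parameters sit ≈0.1 below the parent location; tests
compare against the analytic truncated moments.

What the generator does **not** emulate: correlated sentiments across
actions (real instructions induce correlation; the default is
independent draws), discrete condition designs (give/take framings
come in families, not i.i.d.), non-linear rate–ΔS relations, and
study-level confounds such as country or stakes. Passing recovery
tests therefore show the estimation chain is calibrated *under the
generating model*, not that the linear model is true of real corpora.

The agent-based mode replaces the linear outcome model with softmax
agents under the utility model, grounding the same regression
structure in individual choice; its ground truth records `λ` and `T`
instead of a slope.

## Estimation

Study-level fits are unweighted simple OLS with intercept, in closed
form. A study is pool-eligible only with ≥3 conditions, nonzero ΔS
variance, and a strictly positive slope SE; a perfect (zero-residual)
fit is ineligible because its inverse-variance weight diverges. On the
bundled corpus joined with any outcome data, exactly one study
(Ockenfels & Werner) drops: its scorer returned sentiments giving
constant ΔS = 3.00 in all four conditions.

Pooling is inverse-variance fixed-effects and DerSimonian–Laird
random-effects with Wald-normal CIs at the fixed critical value
1.959964. τ² is the DL moment estimator floored at zero; I² =
max(0, (Q−df)/Q)·100. REML and Knapp–Hartung adjustments are out of
scope; DL + Wald is the convention the analysis follows.

Numerical notes: weights are normalized and checked to sum to 1 within
1e-12; a single-study pooling set returns that study's effect with
Q = 0 and τ² = 0; the permutation and recovery utilities derive all
randomness from explicit seeds.

## Calibration results and known limitations

On 500 synthetic replicates at the default conditions the mean pooled
DL estimate is within 0.001 of the generating slope (unbiased), and
the 95% Wald CI covers the truth for ~90–93% of replicates. The
shortfall from nominal coverage is the well-documented small-k
behaviour of DL with Wald intervals — with 11 studies and slope SEs
estimated from 5 points each, uncertainty in the weights is ignored —
and is reported as measured rather than corrected, since the
Knapp–Hartung remedy is deliberately out of scope.

The permutation sanity check shuffles rates across conditions within
each study and re-runs the full screen-and-pool chain; the pooled z
averages near zero (|mean z| < 0.2 over 200 permutations). Base
corpora for this check are generated under the null (β = 0, τ = 0),
where within-study rates are exchangeable by construction, making the
permutation distribution exactly valid. On signal-bearing corpora
with very small residual noise the permutation mean of z is *not*
zero (≈ +0.16 at the default conditions): permutations that happen to
align with ΔS fit well, get small SEs and hence dominant
inverse-variance weights — a real small-sample property of weighted
pooling worth knowing about when permutation-testing meta-analyses.

Other limitations: the two-stage procedure ignores uncertainty in the
ΔS values themselves (scores are treated as known study-level
covariates); the headline published pooled effect cannot be recomputed
here because the behavioural outcomes it used are not part of the
published score table; and the mock scorer is a pipeline harness, not
a sentiment model.
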