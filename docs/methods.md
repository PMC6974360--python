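# Methods

## Task model

The package simulates and analyses a volatile two-armed bandit with an
advice cue. On each of 120 trials an agent chooses between a blue and a
green option; exactly one is rewarded, with P(blue rewarded) following a
piecewise-constant schedule and P(green) = 1 − P(blue). Before the
choice, a frame "advises" one option; the probability that the frame
marks the to-be-rewarded option follows a second, independent schedule.
Both schedules alternate a *stable* phase (constant probability for
50–60 trials) with a *volatile* phase in which the probability reverses
(p → 1 − p) every 10–30 trials.

Schedule construction: the stable length is drawn uniformly from the
subset of 50–60 that leaves either zero or at least ten volatile trials;
the volatile remainder is partitioned into change intervals drawn
uniformly from 10–30 (the final interval absorbs the exact remainder, and
the draw range is constrained so it always lands in 10–30). Probability
levels default to {0.2, 0.25, 0.75, 0.8}, a set closed under p → 1 − p;
the probability reverses at every segment boundary, including the
stable/volatile boundary. Four canonical layouts — the 2 × 2 crossing of
whether the reward and the advice schedule start stable — are frozen
under fixed internal seeds, so cohorts share the same four schedules the
way participants randomised to pre-programmed schedules would.

Outcomes are drawn per trial as Bernoulli(p) by default; an
`exact_proportion` mode instead shuffles, within each constant-p run, a
vector containing round(length·p) rewarded-blue trials, for workflows
that want realised frequencies to match the schedule exactly. Advice
correctness is drawn the same way from the advice schedule and is defined
against the trial's *realised* outcome: the frame marks the outcome
option when correct and the other option when not.

## Learner and action selector

Two Rescorla–Wagner predictors run in parallel, each updated by the
delta rule V ← V + α(r − V) on every trial (the outcome indicator is
always shown, so both reinforcement signals are observable regardless of
the choice):

* the experienced-value learner tracks V_exp = P(blue rewarded), with
  r = outcome (1 = blue);
* the inferred-value learner tracks V_inf = P(advice correct), with
  r = the advice–outcome agreement indicator.

Each learner uses a phase-specific learning rate, selected by the
volatility label of its *own* schedule at the current trial — four rates
in the full model (stable/volatile × experienced/inferred). Volatility
labels are experimenter-defined inputs, not inferred online. The advice
frame (coded 0 = blue, 1 = green) converts to a blue-reward probability
V_iaw = |advice − V_inf|, which is mixed with the experienced value by
the weight ζ ∈ (0, 1):

    vB = ζ·V_iaw + (1 − ζ)·V_exp.

Choice probabilities follow the unit-square sigmoid
P(blue) = vB^β / (vB^β + (1 − vB)^β) with inverse temperature β > 0
(β = 1 is probability matching; β → ∞ a step function at vB = 0.5).
Prediction at trial *i* uses values formed from trials < *i*
(predict-then-update); both values start at 0.5, so the first trial's
prediction combines the flat initial state with the first advice cue.

Nested variants: M1 constrains all four learning rates equal, M2
separates stable/volatile but shares rates across learners, M3 frees all
four.

Numerical choices: vB is clipped to [1e−12, 1 − 1e−12] before the
sigmoid, and the log-likelihood is evaluated in log-odds space
(log P = −log(1 + e^−βθ) with θ = logit(vB)), which is exact to within
the clip and avoids underflow at large β — a direct evaluation of the
sigmoid underflows to zero near β ≈ 48, the prior mean.

## Estimation

Learning rates and ζ are estimated through the logit transform, β
through the log transform, with Gaussian priors in transformed space:
N(logit(0.2), 1) per learning rate, N(ln 48, 1) for log β, and N(0, 100)
for logit ζ (effectively flat, centred on equal weighting). The
objective is the log-joint posterior, maximised by BFGS with numerical
gradients from a fixed start (learning rates at logit(0.5) = 0, β and ζ
at their prior means; gradient tolerance 1e−6, ≤ 500 iterations). The
default is that single fixed start; optional jittered restarts
(`n_restarts`, SD 1 in transformed space) are available for difficult
sessions, and across the simulations in the test-suite the single start
was never beaten by restarts by more than numerical noise. Saturated
transformed values are mapped to natives clipped at the open-interval
boundary (1e−12) so the optimiser sees a smooth plateau rather than a
cliff, and an exit reporting "precision loss" with a final gradient
max-norm below 1e−3 is treated as converged.

Log model evidence is approximated at the MAP by Laplace:
F = log-joint + (d/2)·ln 2π − ½·ln det(−H), with H the central
finite-difference Hessian (relative step 1e−4). A non-positive-definite
−H is inflated on the diagonal until positive definite and the result
flagged. With no data this F is exactly 0 (the Gaussian prior integrates
to one), which the tests verify.

Group-level comparison uses the random-effects Dirichlet scheme
(variational updates of model frequencies from per-subject evidences),
exceedance probabilities by Monte Carlo over the posterior Dirichlet,
and protected exceedance probabilities via the Bayes omnibus risk, with
the variational free-energy bound for the alternative and the
equal-frequency evidence for the null. Subjects with non-finite
evidences are excluded and reported.

## Win-stay/lose-shift analysis

For each trial after the first, a regressor encodes the strict WSLS
choice given the previous trial: stay with the previous colour after a
win (choice matched the outcome indicator), switch after a loss
(experienced cells, coded 1 = blue); repeat or reverse the previous
follow/deviate decision after a win or loss (inferred cells, coded
1 = follow the frame). Trials are assigned to stable/volatile cells by
the relevant schedule's label *at the predicted trial*; trials just after
a phase switch keep that label and still use the true previous trial.
Each cell's coefficient is the slope of a univariate regression (with
intercept) of the actual coding on the predicted coding. The default
family is linear — for binary codings the OLS slope is the difference of
conditional response means, which keeps coefficients on an interpretable
0–1 scale — with logistic regression available by flag, because the
field uses both and the two orderings agree in the simulations we ran.
Cells with fewer than 10 usable trials or a constant predictor/response
are reported as missing with the reason. Raw win-stay and lose-shift
proportions per cell are exported alongside.

## Optimal-learner analysis

Task-optimal parameters are the averaged MAP estimates obtained by
fitting the full model (standard priors) to responder sequences on 100
synthetic sessions cycling the four schedule layouts. The default
responder is *probability matching*: choice ~ Bernoulli(schedule p_blue)
per trial. We also implement the deterministic alternative (always pick
the option with p > 0.5, ties repeating the previous choice; this is the
sequence that defines accuracy). The stochastic responder is the
default because it is the self-consistent reading of fitting a softmax
observer to "optimal" behaviour: fitted to deterministic responses the
inverse temperature is pushed toward the step-function regime (β ≈ 3.1
in our runs) and the volatile-phase experienced rate absorbs the
post-reversal switching (≈ 0.29), whereas the probability-matching
responder yields the moderate β ≈ 1.2 and learning rates ≈ 0.16–0.24
that characterise a soft ideal responder on this task; the latter
regime matches the published task-optimal reference values this analysis
is meant to reproduce. "Distance from optimal" is the signed difference
fitted − optimal per parameter (absolute by flag).

## Synthetic cohorts and recovery studies

`make_cohort` simulates two sessions per subject with identical
schedules but independently drawn outcomes, advice and choices.
Generating parameters are sampled per subject from configurable ranges;
the defaults are α_stable ~ U(0.10, 0.40) and α_volatile ~ U(0.20, 0.60)
for both learners (so the volatile−stable gap is positive on average,
the pattern the model family is designed to detect), β ~ U(1, 6),
ζ ~ U(0.2, 0.8).

Parameter recovery refits each subject jointly over their two sessions
(240 trials) and reports per-parameter bias, RMSE and Spearman
correlation; at 60 subjects all six parameters recover with rank
correlations above 0.6, ζ highest. Model recovery simulates 20 subjects
per generating variant at discriminable parameter values (M3 crosses the
experienced/inferred rates so M2's equality constraint is genuinely
violated), fits all three variants per subject, and selects by Laplace
evidence; the confusion-matrix diagonal dominates every row.

What the synthetic data do not emulate: drug effects (sessions are
labelled A/B abstractly), social versus non-social framing (a label
only), within-session non-stationarity of human engagement, and
individual deviations from the generative model family. Passing
recovery tests therefore show the estimation machinery is faithful to
this model class on this task structure, not that human data are
generated by it.

## Problem sizes and determinism

Default analysis sizes — 100 optimal-learner datasets, 60-subject
recovery cohorts, 20 subjects per generator for model recovery — follow
the published analysis scale where one exists and otherwise were chosen
as the smallest sizes at which the reported statistics are stable across
seeds. All generators and fits are bit-reproducible given a seed; the
BFGS start is deterministic, so fits are reproducible even without one.

## Known limitations

* The exact four schedules of the original task are not public; the
  canonical layouts here reproduce their statistical structure
  (phase lengths, reversal intervals, probability levels), not their
  trial-by-trial values.
* The Laplace approximation ignores variational correction terms a full
  free-energy evidence would include; comparisons are internally
  consistent because the same approximation is applied to every variant,
  and model-recovery simulations back the selection behaviour.
* Fits are per subject (optionally pooling sessions); there is no
  hierarchical shrinkage across subjects.
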