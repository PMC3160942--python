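# Methods

## The assignment model

The engine is a naive-Bayes classifier over a condensed cause list. Each
cause *c* has a prior π(c) and an emission probability p_ic = P(indicator
*i* present | cause *c*). For a death with ternary indicator vector *s*
(present / absent / unknown), the unnormalised score is

    score(c) = π(c) · Π_{i: s_i = present} p_ic · Π_{i: s_i = absent} (1 − p_ic)

and the posterior is the normalised score. Unknown indicators contribute
nothing — the standard naive-Bayes treatment of missingness, which also
makes indicators that a questionnaire never collected harmless. The product
is accumulated in log space; a profile with zero likelihood under every
cause raises a degenerate-posterior signal and the death is reported
indeterminate. The log-space and direct-product formulations are verified
equivalent to 1e-9 in the test suite.

**Prevalence flags.** Two causes whose prevalence varies by an order of
magnitude or more between settings (HIV, malaria) accept a high/low flag
that multiplies their prior by a configurable factor (defaults 5 and 0.2)
before renormalisation. The defaults are an order-of-magnitude spread
chosen once; nothing downstream is sensitive to the exact value when
indicators are informative, because the likelihood dominates the prior.

**Reporting policy.** A cause is reported only if its normalised posterior
reaches `top_min` (default 0.4); a second or third cause is added only if
it also reaches `extra_frac` (default 0.5) times the top cause's posterior.
Ties are broken by cause-list order, making batch runs deterministic. The
thresholds of the original proprietary interpreters are not public; these
defaults produce a predominantly single-cause output mix, which is how
such interpreters behave in practice, and both knobs are configurable.
When validating against a reference method only, a death whose top cause
disagrees with the reference but whose second or third cause matches it is
credited with the matching cause; this resolution applies before
dichotomisation in the validity tables and is used nowhere outside
validation.

**Percentage convention.** Printed percentages use round-half-up (CSMF to
one decimal, output mix to integers). Round-half-even (Python's default)
is never used for reporting.

## The synthetic cohort

The generator emulates a hospital-anchored validation study: *n* deaths
with true causes iid from a specified CSMF; indicators drawn Bernoulli from
the emission matrix, each flipped with probability `flip_noise` and masked
to unknown with probability `missing_rate`; and two imperfect raters — a
hospital-style rater and a physician-coder-style rater — drawing their
verdict from a row-stochastic confusion matrix over the true cause, with an
optional unconditional indeterminate rate. Age (normal, mean 55, SD 20,
truncated to 15–100) and sex (56% male) are generated only as stratifiers;
indicators do not depend on them.

The emission matrix used for simulation is a **signature-block** design:
indicators are randomly partitioned into per-cause blocks, a signature
indicator fires with probability 0.5 + 0.5·informativeness for its cause
and 0.5·(1 − informativeness) otherwise. This gives `informativeness` a
monotone meaning — 0 is pure noise, 1 a deterministic barcode — which the
parameter-recovery tests exploit. One global seed is split into per-stage
substreams (matrix, cohort, each rater, bootstrap) via `SeedSequence`, so
stages can be re-run independently and full runs are byte-identical.

**Default study conditions.** 145 deaths, ten condensed causes with the
five classical leading adult causes (HIV/AIDS, cardiovascular disease,
pulmonary TB, meningitis, diabetes) jointly at 73% of deaths; 60
indicators at informativeness 0.8; flip noise 0.05 and missingness 0.10;
hospital rater 95% accurate, physician rater 70% accurate with a 1%
indeterminate rate; HIV and malaria flagged high. The parameter-recovery
check uses the same conditions at n = 1000. These sizes keep the full
suite and the acceptance script in the low seconds.

**What passing does and does not show.** Indicators are conditionally
independent given the cause — exactly the engine's own assumption — so the
synthetic studies measure correctness of the statistical machinery and
behaviour under noise/missingness, not real-world accuracy. Real VA
symptoms are correlated (e.g. fever clusters), real raters err
systematically rather than uniformly, and real cause lists are far more
imbalanced; none of that is emulated. The engine-vs-reference kappa here
is accordingly optimistic relative to field studies.

## Cause recoding

Labels are matched case-insensitively on trimmed strings; no fuzzy
matching, so every recode is auditable. Unmapped labels fall into a
configurable default category with a logged warning rather than aborting a
batch, since low-frequency diagnoses are expected to be regrouped. The
shipped 35-entry condensed list is a synthetic stand-in assembled for this
package: it contains every category the built-in recoding rules target,
padded with the usual broad adult cause groups; users with a fuller label
inventory supply their own map CSV. Recoding is idempotent, and
`indeterminate` passes through unchanged.

## Agreement statistics

- **CSMF**: per-category fraction including indeterminate, with a
  per-cause absolute-difference check against the gold CSMF at a
  configurable tolerance (default 5 percentage points).
- **Cohen's κ**: computed from the K×K cross-classification; the 95% CI
  uses the large-sample Fleiss–Cohen–Everitt variance, truncated to
  [−1, 1]. κ is undefined (explicit error) when chance agreement is 1.
- **Multirater κ**: Fleiss' kappa over three raters; CI by subject-level
  bootstrap (default 2000 resamples, seeded). A bootstrap resample that
  happens to be unanimous is scored κ = 1.
- **Validity metrics**: one-vs-rest 2×2 per cause; sensitivity,
  specificity, PPV, NPV as percentages with exact (Clopper–Pearson)
  binomial CIs; a zero-denominator metric is reported as not applicable,
  never as 0.
- **Verbal κ scale**: poor < 0.21, fair to 0.40, moderate to 0.60, good to
  0.80, very good above — band upper bounds inclusive.
- **Indeterminate convention**: an indeterminate verdict never counts as
  agreement, not even with another indeterminate (each method's
  indeterminates are relabelled to a method-specific sentinel before
  tabulation). A `drop` policy that removes affected deaths is available;
  the conservative mismatch policy is the default.

## ROC

For hard categorical methods the curve is built from one operating point
per cause — FPR = 1 − specificity, TPR = sensitivity from that cause's
one-vs-rest 2×2 — anchored at (0,0) and (1,1), sorted by FPR, and
integrated by trapezoid. This is the only construction available for a
physician coder, which produces no scores; it is the default reported
curve. For the engine a score-based curve over all pooled (death, cause)
one-vs-rest pairs is also computed by threshold sweep; its trapezoidal AUC
equals the Mann–Whitney concordance probability (ties count half), which
the tests verify by brute force. No binormal smoothing is applied —
smoothing would invent information. A cause absent from the gold standard
has undefined sensitivity; its point is skipped with a warning. Overall
performance is called adequate when AUC strictly exceeds 0.75.

## Design choices and limitations

- The five most common causes for the validity tables are selected by
  gold-standard CSMF rank with ties broken by category order.
- Sex-stratified kappas are computed by filtering before tabulation, with
  no small-sample correction; at n = 145 the female/male strata are small
  and their CIs correspondingly wide.
- The per-cause operating-point ROC for categorical methods is a
  documented interpretation; other constructions (e.g. averaging
  per-cause AUCs) would give different numbers.
- The engine accepts any user-supplied probability matrix in the CSV
  format; it does not reproduce any proprietary interpreter's internal
  probability tables or letter-grade likelihood encoding.
- Bootstrap and rater simulation are the only stochastic components
  besides the cohort draw; all are driven by the single study seed.
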