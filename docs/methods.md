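# Methods

This note documents the models and procedures implemented in `regaze`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the design choices made where the design was
genuinely open.

## Surface word features

Tokenization treats each input line as a verse line. Edge punctuation is
stripped; internal apostrophes are kept, so contractions ("body's",
"trimm'd") are single tokens. Hyphenated compounds are one token by
default; `split_hyphens=True` splits them — the setting matters for
matching word counts across editions (the two bundled sonnets hold 200
tokens with compounds whole and 202 with them split). Tokens with no
letters are dropped; an `exclude` list can remove individual positions.

- **wl** counts letters only (apostrophes and hyphens excluded).
- **logf** is log₁₀(count + 1) against the lexicon, so an
  out-of-vocabulary word scores 0. Log base and smoothing are
  conventions; base 10 keeps values in a 0–6 range for realistic corpora.
- **on** (Coltheart's N) counts lexicon types of identical length at
  Hamming distance exactly 1; **hfn** is the subset with strictly
  greater frequency, so hfn ≤ on always.
- **odc** is the mean Levenshtein distance from the word to every
  *other* lexicon type, type-weighted (distance is a property of word
  forms, and no weighting is implied by its definition). The edit
  distance is an iterative DP implementation, tested against an
  independent recursive oracle; the scan is exact, O(|types|) per word.
- **cvq** divides consonants by vowels over {a,e,i,o,u}; "y" counts as
  a vowel only when the word has no other vowel ("rhythm" → 5.0). A word
  with no vowel even then yields NaN with a warning.
- **sonscore** sums per-letter ranks on the 10-level sonority hierarchy
  (vowels high, voiceless stops low) and divides by √wl; "art" →
  (10+7+1)/√3 = 10.39. The default table is letter-based. Letters
  without a rank in the phoneme hierarchy are mapped by their most
  common English realization: c, q, x → 1 (as /k/), h → 3 (voiceless
  fricative row), y → 8 (as the glide /j/). A `phonemic` flag collapses
  "ng" to a single nasal segment; fuller grapheme-to-phoneme conversion
  is out of scope and the hook exists for callers who have one.

## Gaze measures

A word's **first pass** is the maximal run of consecutive fixations on
the word starting at its first fixation; the pass ends at the first
fixation on *any other word*. Fixations outside all interest areas do
not end a pass and are otherwise ignored (not imputed). FFD is the first
fixation of the pass, GD the pass sum, RT everything on the word after
the pass, TRT = GD + RT exactly. Skipped words are missing values, never
zeros, so per-word duration means aggregate over fixating participants
only; fixation probability is the share of participants who fixated the
word. Assignment expands boxes vertically by `slack_px` (default half
the generator's inter-line gap, 11 px at 44 px line pitch) to absorb
vertical drift; when slack makes several boxes eligible the vertically
nearest wins. No minimum-duration filter is applied by default (tracker
preprocessing typically happens upstream); a threshold is available.

The first-pass segmentation is verified against a brute-force oracle
that enumerates passes explicitly, exhaustively for all scanpaths of
length ≤ 5 over 3 words and on random scanpaths of length ≤ 12 over 4.

## Questionnaire statistics

Paired t-tests (two-sided, df = n−1) compare session means of the two
5-point ratings; a zero-variance difference vector is an error, not a
statistic. Topic identification enters as a pre-coded boolean (expert
adjudication of free-text answers is a human step outside the package).
Bowker's symmetry test is χ² = Σ_{i<j} (n_ij − n_ji)²/(n_ij + n_ji) over
informative cell pairs, df = their number; for a 2×2 table this is
McNemar's test. No continuity correction is applied: the uncorrected
form is what reproduces χ² = 8 from discordant cells (15, 3), the
unique cell configuration consistent with right/wrong marginals
30/20 → 42/8 together with an integer-valued χ² statistic.

## Rereading mixed model

Each measure is modeled as `response ~ session` with a random intercept
per word, fitted by REML (statsmodels MixedLM). Word identity is the
(poem, line, word-position) key, which realizes nesting within poem.
Session is coded first = 0 / last = 1 and the reported estimate is the
first − last contrast. Boundary fits (zero word variance) keep their
estimates with a warning; only non-finite fits raise. With no between-
word variance the estimator collapses to the mean paired difference,
which the tests verify.

## Predictive modeling

Predictors and response are z-scored per session. The cross-validation
harness re-partitions rows into k = 10 folds with a seeded shuffle every
repetition (100 reps by default), fits on k−1 folds and scores the
held-out fold. Held-out R² uses the test fold's own mean in the SST term
— the choice is documented because alternatives (training-mean SST)
exist; fold-local SST is the stricter and more common convention.
Summaries report mean and SD over all k × reps fold scores.

The nonlinear family is a single-hidden-layer tanh network (3 units,
linear output) trained by L-BFGS with analytic gradients on

    loss = ½·mean(r²) + λ·‖θ‖²,

best of 5 seeded restarts, bit-reproducible given a seed. The penalty is
on the mean-loss scale so λ is sample-size free. λ defaults to 0.02,
set by synthetic recovery studies: values in roughly [0.005, 0.025]
recover planted feature importances stably (20/20 seeds), and the upper
end of that plateau also maximizes held-out R² on the default synthetic
world; the choice is a plateau, not a knife edge. A unit test
cross-checks the network against sklearn's MLPRegressor with matched
architecture (same training R² within 0.02); sklearn is not used for
the fits themselves because its per-fit cost would dominate the
100×10-fold budget.

## Total-effect feature importance

FI is the Sobol total-effect index of each predictor of the *fitted*
model, estimated by a Jansen-type scheme on resampled rows: two
bootstrap row samples A, B of the observed predictor table, and for
predictor j

    T_j = mean[(f(A) − f(A with column j from B))²] / (2·Var f),

clipped to [0, 1], with a Monte-Carlo SE from ≥ 10 independent re-draws.
Resampling whole rows keeps the empirical joint distribution of the
correlated predictors in the base samples; only the replaced column is
decoupled. On additive models with independent predictors the estimator
matches the analytic variance shares within 0.03 (tested). FI > 0.1
flags a predictor as important (strict inequality).

**A caveat the package makes explicit:** with predictor collinearity as
strong as the empirical feature structure (|r| up to ~0.85 between word
length and its neighbors/frequency), the per-feature FI of a model
*refitted* at n ≈ 200 is not identifiable — word length's unique signal
falls below the noise floor, so even ordinary least squares may assign
it a near-zero coefficient and any well-fitting model may route its
contribution through correlated proxies. The total-effect estimator is
not at fault (applied to the true generating function it recovers the
planted indices); the fitted model is genuinely underdetermined.
Importance-recovery tests therefore use `fi_recovery_config()`, a world
with the same correlation signs capped at |r| = 0.5, where the truth is
identifiable. Real-data FI values under strong collinearity should be
read as properties of the particular fitted model, not of the features.

## Synthetic data

The generator states a small world patterned on a two-poem rereading
experiment; its defaults are the published descriptives of that design
and are not tuned per run.

- **Features**: Gaussian copula over the seven features with the
  published correlation matrix as target (it is positive definite as
  printed). Because quantile transforms to discrete/clipped marginals
  attenuate Pearson correlations, latent correlations are pre-adjusted
  by NORTA matching (pairwise bisection on a fixed probe sample,
  nearest-PD projection). One target, r(wl, on) = −0.85, is infeasible
  for right-skewed marginals under negative dependence (Fréchet bound
  ≈ −0.81 after matching); the generator takes the nearest attainable
  value and warns. Marginals: wl integer 1–12 (lognormal), logf 0–5,
  on a rounded gamma, hfn a rounded exponential with mean 0.55 (the
  published mean) clamped to ≤ on, odc ≥ 1, cvq and sonscore positive.
- **Response**: standardized-scale signal
  wl − 0.8·logf − 0.3·on + 0.3·sonscore + 1.5·wl·logf (z-scores), with
  noise set so the signal explains 60 % of response variance. The
  interaction weight makes the non-linearizable share ≈ ⅓ of the
  signal, matching the published held-out gap between the network and
  least squares on total reading time; with a weaker interaction a
  3-unit network cannot beat OLS at n = 202, which is itself an
  informative boundary.
- **Scanpaths**: one left-to-right pass per line; a word is skipped with
  probability logistic(α₀ − wl_z + logf_z), α₀ calibrated by bisection
  to the session skip rate (13 % first, 20 % last). Fixated words get
  1–2 first-pass fixations with Gamma durations (shape 8, mean 257 ms ±
  feature effects). After the pass each fixated word is revisited with
  probability 0.7 (first session), adding Gamma regression fixations of
  mean 395 ms; the last session multiplies the probability by 0.45 and
  durations by 0.80, so expected regression time falls to 0.36 of the
  first session (415 → 149 ms), and only late measures carry the
  session effect — first-pass measures are session-invariant by
  construction. Words are laid out left-aligned on a 1024×768 canvas
  (13 px character cells, 44 px line pitch) and coordinates jittered
  inside boxes.
- **Ratings**: discretized normals (round, clamp to 1..5) with a shared
  participant×poem latent giving within-pair correlation 0.5; session
  means 3.78 → 3.18 (willingness) and 3.32 → 3.52 (appreciation), SD
  ≈ 1. Clamping biases means toward the scale center by a few
  hundredths at these settings. Topic correctness is a paired Bernoulli
  (first-session accuracy 0.6; wrong→right 0.7, right→wrong 0.05).

What the generator does **not** emulate: cognitively plausible saccade
programming (no landing-position distributions, no parafoveal preview),
within-session rereading loops, participant-level random slopes,
fatigue or order effects, and any semantic or supra-lexical structure.
A green recovery test therefore establishes that the pipeline measures
what the generator planted — not that the generator is a model of
readers.

## Numerical choices

- Seeds: every stochastic component takes an explicit seed;
  per-repetition CV streams are spawned via `SeedSequence` so results
  are order-insensitive and bit-reproducible (tested end to end).
- z-scoring uses the population SD; constant columns raise.
- Degenerate inputs fail loudly: empty poems, overlapping interest
  areas, non-increasing fixation order, zero-variance paired
  differences, all-concordant symmetry tables, constant-output models.
- The 2×2 McNemar p-value uses the χ² approximation; for very small
  discordant counts an exact binomial is preferable (the test suite
  checks agreement of rejection decisions for b + c ≥ 10).

## Limitations

- The network architecture (3 tanh units, L2 penalty, 5 restarts) is a
  fixed, deliberately small family; no hyperparameter search is done.
- Total-effect FI under dependent predictors has no unique
  decomposition; see the caveat above.
- The tokenizer is rule-based for English verse; it does not handle
  enjambment markers, stage directions, or non-Latin scripts.
- Lexicon-based features depend entirely on the supplied frequency
  list; none is bundled.
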