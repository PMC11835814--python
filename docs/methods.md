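# Methods

## The experiment being modeled

An adult male Bengalese finch sings bouts of syllables whose order follows
a probabilistic syntax. One branch point `x` with several successors is
chosen; one successor `a` (the *target branch*) is punished: whenever the
bird sings `x → a`, a 40 ms white-noise (WN) burst is played, except on a
random 10% of renditions (*catch trials*), which are used to measure
learning without the acoustic confound of the stimulus itself. A block
consists of one baseline-screening day (BS), four to five training days
(T1–T5), a post-screen the next day (PS1) and two more one and two weeks
later (PS2, PS3). Each bird runs three blocks, one per social context
(male alone MA, male–female MF, male–male MM), in an order balanced across
birds.

## Statistics implemented

- **Transition table.** Every occurrence of the branch syllable is one
  *rendition*; its outcome is the next syllable, or `END` when the bout
  ends there. End-of-bout is a first-class outcome (configurable off).
  TPs are outcome counts divided by rendition count.
- **Degree of learning.**
  `Learning[%] = 100 − (TP_best / TP_baseline · 100)`, catch trials only
  on training days. *Design choices the source protocol leaves open:*
  the "best" training day is the day with minimal catch-trial TP (ties go
  to the earliest day); baseline TP uses **all** BS renditions, since no
  feedback — and hence no catch/non-catch distinction — exists on screen
  days. Negative values (worsening) are allowed.
- **Transition entropy.** Per bout: for each syllable type `b`,
  `H_b = −Σ_i P(i) log P(i)` over its within-bout successor distribution
  (END included), and `TE = Σ_b H_b P(b)` with `P(b)` the frequency of `b`
  among transition-emitting positions. The log base defaults to 2 and is
  recorded in every output; base-e values equal base-2 values times ln 2.
  Entropy is computed on raw syllable tokens, not on merged chunk states.
- **Song rate**: bouts starting within the half-open window
  [9:30, 17:00) of a given day.
- **Song speed**: duration (first onset to last offset, gaps included) of
  a stereotyped syllable sequence ("chunk"); matching is exact-token,
  leftmost, non-overlapping.
- **Early learning**: TPs in consecutive 50-bout bins within the first
  training day; cross-context comparison uses the last complete bin of
  the context with the fewest bouts, the same bin index everywhere.
  **Relative learning speed** is the degree of learning divided by the
  total bout count over the block's training days (the protocol does not
  pin down "total song rate"; total training-day output is used here).
- **Targeting accuracy**: hits / (hits + false positives + misses) · 100,
  catch trials excluded from the denominator. Training days under 75% are
  excluded from the learning analysis.
- **Bout segmentation**: a silent gap ≥ 2 s starts a new bout (the
  comparison is `≥`, configurable); a file boundary always ends a bout;
  segmentation is per singer and per file, so files of two birds that
  interleave in time segment independently.
- **Mixed-singing exclusion** (MM context): per file, the overlap between
  the partner's syllable intervals and the subject's bout spans, as a
  fraction of the subject's total bout duration; files above a threshold
  (default 0 — any overlap excludes) are dropped entirely, as are
  partner-only files. The protocol reports only resulting exclusion
  percentages, so the rule itself is an operationalization.

## Statistical tests

Proportion tests are continuity-corrected chi-square on 2×2 tables (the R
`prop.test` convention). One-way ANOVA uses explicit sums of squares with
Tukey-Kramer adjusted pairwise comparisons. The three-factor analysis of
degree of learning (context, order, subject) fits **main effects only**:
with 6 subjects × 3 contexts there are 18 observations and the error
df is 18 − 1 − (2 + 2 + 5) = 8; interaction terms would exhaust the data.
Paired t-tests are two-sided; Pearson correlation reports df = n − 2.
Degenerate inputs (constant response, zero-variance differences, empty
margins) return statistic 0 and p = 1 with a `degenerate` flag rather than
NaN.

## The simulator

Song is a first-order Markov walk from a start token until `END` or a
length cap, with Gaussian syllable/gap durations. The default grammar —
intro notes `i`, branch `x → {a: 0.7, l: 0.28, END: 0.02}`, and a
stereotyped chunk `b c` returning to `x` — produces bouts of ~100
syllables (~12 s) containing ~25 branch renditions, i.e. long Bengalese
bouts in which the branch recurs many times. Bouts are serialized in time
(one file per bout) across a 9:00–17:30 singing day.

**Feedback.** Per rendition: with probability 0.10 it is a catch trial
(no WN); otherwise WN is delivered with probability 0.93 on target
outcomes (matching the reported ~93% average template accuracy) and 0.005
on non-target outcomes. **Learning** is a multiplicative decrement: WN on
a target rendition updates `p ← max(floor, p·(1−η))` with η = 0.05,
redistributing the removed mass proportionally over the other outcomes,
so the branch row stays a probability distribution and the expected
trajectory is available in closed form for tests. False positives are
assumed non-instructive (a simplification). On feedback-free days the
target probability relaxes toward baseline at 25%/day, compounded over
elapsed calendar days, emulating the return to baseline across
post-screens. Each context block starts from the pristine grammar
(complete washout between blocks, which are weeks apart).

**Context profiles** emulate the observed context effects: daily bout
counts (negative-binomial, dispersion 30) of 300 (MA), 170 (MF), 180 (MM)
— singing roughly halved in social housing; tempo factors 1.0 / 0.98 /
0.96 (social song slightly faster); entropy pull 0 / 0.02 / 0.02 (no
measurable sequencing-variability change). Context differences in
*asymptotic* learning are generated by scaling the floor: with baseline
TP 0.7 and floor 0.15, factors 2.85 / 2.52 / 1.70 put the expected
reductions near 39% / 46% / 64% (MM > MF > MA). Between-subject variation
multiplies each floor by a lognormal jitter (σ = 0.15). η, the floor and
the relaxation rate are free parameters — the behavioral data constrain
the size of the reduction, not the per-experience mechanism. In the MM
context 3% of recorded files also contain an overlapping partner bout,
exercising the mixed-singing exclusion at realistic (few-percent) rates.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analysis assumes:
Markov branch syntax, catch-trial scheduling, imperfect targeting,
context-dependent rate/tempo/learning, mixed MM files. Passing tests
therefore demonstrate that the pipeline recovers programmed effects at
realistic sample sizes — not that real birds obey a first-order Markov
model, a multiplicative learning rule, or context effects of these sizes.
Real song has acoustic segmentation ambiguity, annotation errors,
higher-order and repeat-dependent syntax, and within-day nonstationarity
that the generator deliberately omits.

## Numerical and scale choices

Estimation noise on the learning scale is dominated by the catch-trial
count of the best training day; the "minimum over days" selection also
biases the estimate upward by roughly one standard error when the
trajectory has plateaued. At the default conditions (~200 bouts/day,
~25 renditions/bout, 10% catch) the recovery tests run at ~1,000 bouts
per context block and resolve learning to a few percentage points. Null
calibrations use 1,000–2,000 simulations per test; randomized oracle
comparisons use 100 instances per operation. Probability rows are
validated to sum to 1 within 1e-9 and renormalized after each update.
Ties in best-day selection go to the earliest day; empty transition
tables are flagged undefined rather than returning NaN silently; the
proportion test's continuity correction is switched off in null
calibration because the Yates statistic is deliberately conservative on
discrete data.

## Known limitations

- The learning rule is one plausible mechanism chosen for closed-form
  testability; the analysis never depends on it, but parameter-recovery
  results do.
- Chunk/state discovery (merging stereotyped sequences into single syntax
  nodes, splitting repeat states) is out of scope; entropy on raw tokens
  is therefore not numerically comparable to chunk-level entropy.
- The CLI analyzes one dataset directory per config; multi-study
  meta-analysis, plotting, and audio-level processing are out of scope.
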