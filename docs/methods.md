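# Methods

This note documents the statistical procedures, the synthetic data model,
the defaults that matter, and the numerical choices — in the package's own
terms. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

A transcript is an ordered list of *talk turns* — maximal same-speaker
spans, bounded by a change of speaker — with start/end offsets in float
seconds (inputs in `mm:ss` are converted on read). Consecutive same-speaker
rows are merged on read (texts joined by a space, time span unioned), so
"turn" always means a maximal span and every analyzed transcript strictly
alternates speakers. Text is UTF-8, normalized to Unicode NFC and otherwise
untouched. Validation reports problems (reversed times, overlaps, PHQ-9
outside 0–27, duplicate dyads, secondary sessions whose therapist is absent
from the primary sample) without dropping sessions.

Tokenization lowercases, folds the typographic apostrophe onto `'`, takes
maximal runs of word characters and apostrophes, and strips edge
apostrophes — so contractions (`i'll`, `let's`, `y'all`) survive as single
tokens. No lemmatization or negation handling.

## Features

Eighteen features; fourteen are lexicon counts reported as proportions of
words in the window, four are paralinguistic. Sixteen are per-speaker; the
two therapist-to-patient ratios need both speakers and are excluded from
per-speaker series and signatures. Matching modes: exact token, wildcard
(terminal `*` = stem prefix), and phrase (greedy non-overlapping
left-to-right scan, longest entry first, ties lexicographic; one count per
occurrence, with the denominator remaining total words).

The built-in lexicons are deliberately small stand-ins (the published
example terms per feature); the full LIWC dictionary and NRC emotion
lexicon are proprietary/externally licensed and must be supplied by the
user (`.dic` / TSV loaders). **Feature magnitudes computed with the
stand-ins are not comparable to values computed with the full
dictionaries** — all distributional analyses in this package are
dictionary-relative.

Windowing: a turn belongs to exactly one quintile, decided by its temporal
midpoint (turns are never split, so words and seconds stay unfragmented); a
midpoint exactly at session end clamps to quintile 5. Zero-denominator
policy: proportions over zero words are 0; rates over zero seconds are
missing; windows without turns for a speaker are missing; ratios with a
missing or zero denominator are missing. Missing values propagate as
exclusions, never as zeros.

Per-turn lexicon features are proportions rather than raw counts so that
turn length does not masquerade as responsiveness downstream.

## Timing analysis

Per feature and role, the per-session quintile values (one observation per
session) feed Mann–Whitney U tests: first vs. last quintile within role,
and therapist vs. patient within the first and within the last quintile.
All contrasts of one run form a **single declared BH-FDR family** at
α = 0.05 — conservative and reproducible, given that family boundaries are
otherwise arbitrary. Sessions are treated as independent samples; the
paired Q1/Q5 structure within a session is deliberately ignored to match
the unpaired test choice.

Mann–Whitney: U is rank-based with ties counting ½. For pooled n ≤ 12 the
two-sided p comes from exact enumeration of all group labelings (valid
under ties; two-sided via distance from the null mean n₁n₂/2, using the
symmetry of U under value negation); otherwise the normal approximation
with tie-corrected variance and continuity correction.

Alignment labels derive from the therapist-vs-patient contrasts:
significant early only → convergent; late only → divergent; both →
parallel-distinct; neither → indistinct.

Quintile curves are smoothed for display with an interpolating natural
cubic spline (zero second derivative at both ends) on the five ordinal
quintile points, and min-max normalized per feature across those five
aggregate means.

## Responsiveness analysis

Each session's alternating transcript becomes T *exchanges* — (patient
turn, therapist turn) pairs, dropping an unmatched leading therapist or
trailing patient turn. The stacked 32-column per-turn feature matrix is
first-differenced to remove macro-level trends, then screened; a session is
excluded when (in order of precedence) it has fewer than `min_exchanges`
(default 10) exchanges, any column has zero variance (or non-finite
values — a degenerate measurement is treated the same way) before or after
differencing, or any differenced column fails the augmented Dickey–Fuller
test. ADF uses a constant, fixed lag order 1, and the MacKinnon approximate
p-value; stationary ⇔ unit root rejected at α = 0.05. Series shorter than
21 exchanges cannot be ADF-tested and skip that screen.

Discovery is a two-stage conditional-independence procedure in the PCMCI
family:

1. **PC1 condition selection** per variable over all lagged candidates
   (lags 1..τ_max, all 32 variables): iteratively re-test each surviving
   candidate given the q strongest other survivors at `alpha_pc`
   (default 0.2), q increasing until it exceeds the survivor count; sort
   strength is the minimum |partial correlation| seen.
2. **MCI tests** for each patient-feature → therapist-feature pair at lags
   0..τ_max (default τ_max = 2): partial correlation of the lagged source
   and the target, conditioning on the target's parents and the source's
   parents shifted by the lag. All lags share a common sample start
   (τ_max + τ) so p-values are comparable across lags.

Lag 0 is tested only in the patient→therapist direction: the patient turn
of an exchange precedes the therapist turn in time, so a contemporaneous
(within-exchange) dependence is temporally ordered. Therapist→patient links
are estimable with the same machinery but are not part of the reported
family.

Partial correlation: least-squares residualization on conditioners plus
intercept, Pearson correlation of residuals, two-sided t test with
n − |Z| − 2 degrees of freedom. Residual sums of squares within rounding
noise of zero are treated as degenerate (ρ = 0, p = 1).

Per dyad, the 16 × 16 × (τ_max + 1) p-values form one BH family at
α = 0.05 (`fdr_scope="per_dyad"`; a pooled `"global"` family across dyads
is available for sensitivity analysis). A feature pair is significant when
any lag survives; the reported coefficient is that of the surviving lag
with the largest |ρ|, ties to the smaller lag. Aggregation counts, per
(source, target) pair, the dyads showing it, with the mean ρ and sign
breakdown, filterable by a minimum dyad count.

## Consistency analysis

Signatures (16 whole-session therapist features) are z-scored per feature
using primary-session mean and **sample** (n−1) sd; secondary sessions are
transformed with the primary parameters. Standardization is required for
vector correlations to be meaningful — otherwise the two large-scale
paralinguistic components dominate every Pearson correlation. A geometric
consequence worth knowing: after column-centering across n sessions, the
*expected* between-signature correlation is slightly negative
(≈ −1/(n−1) ≈ −0.013 at n = 78), not zero.

Between-correlations cover all unordered distinct-therapist primary pairs
(C(78,2) = 3003 at the default geometry); within-correlations pair each
secondary session with its therapist's primary session (20). The two
distributions are compared with Welch's unequal-variance t (df by
Welch–Satterthwaite) — the pooled-variance t would be inappropriate at a
3003-vs-20 size imbalance. Means carry normal-approximation 95% CIs
(± 1.96 se). Pairs with a constant vector are skipped with a warning; both
samples constant with equal means → t = 0, p = 1.

## Classification

Tasks: diagnosis (depression = 1 vs. eating disorder = 0; unknown excluded)
and severity (PHQ-9 ≥ 10 = 1; missing PHQ-9 excluded from this task only).
The model is logistic regression with an L2 penalty λ = 1 on the weights
(never the intercept), fit by damped Newton iterations to gradient norm
1e-8; the ridge term keeps separable ~44-row training halves estimable.
Features are standardized with training-half statistics inside each split.

Evaluation: `n_repeats` (default 1000) random unstratified 50/50 splits
(odd n gives the training half the extra row; single-class training halves
are redrawn, up to 100 times). Chance is the majority-label share **of the
evaluation half**. The empirical p is the fraction of repeats with model
accuracy − chance ≤ 0 (configurable to strict <); the CI on the difference
is the 2.5/97.5 percentile of the per-repeat differences. Note this
evaluation is anti-conservative under the null (the majority baseline is a
hard target to beat *consistently*, so the ≤-0 share can fall below 0.05
somewhat more than 5% of the time); the recovery tests account for that.

## Synthetic data model

Per session with T exchanges, each of 16 features per speaker has a latent
intensity following, for exchange t:

    patient:   x_t = a·x_{t−1} + m_p·(t/T) + ε
    therapist: y_t = a·y_{t−1} + Σ c·x_{src, t−lag} + δ + b(therapist) + m_t·(t/T) + ε

with AR coefficient a = 0.3, noise sd 0.4, trend slopes m, fixed
therapist-vs-patient baseline shifts δ, per-therapist signature offsets
b ~ N(0, σ_b²) shared across that therapist's sessions (plus a
diagnosis-linked shift for depression sessions), and planted cross-links c.
Constant inputs inside the recursion are amplified by 1/(1−a) in steady
state; calibrations below account for that.

Realization is at the word level so tokenization and matching are exercised
end to end: word count per turn is 1 + Poisson(rate), rate modulated by the
seconds-per-turn latent; each word slot emits a term of feature f's
stand-in lexicon with probability base_f · logistic(latent_f), else a
filler token from a fixed non-lexicon vocabulary; phrase features emit
their full phrase. Turn duration is words / (2.0 · exp(0.25 ·
latent_wps)) words-per-second, so observed words-per-second is an exact
monotone readout of its latent — the cleanest channel for planting
dependence links. Emission vocabularies are disjoint across features
(Personal Pronouns emits only third-person singular forms), though emitted
phrases can contain pronoun tokens, which induces small realistic
correlations between tactic and pronoun features. PHQ-9 is
round(27·logistic(s)) with s ~ N(−1, 0.9) and ~10% missingness; diagnosis
labels are assigned 50/50.

The `paperlike` preset encodes the study conditions the package is built
around: 78 primary + 20 secondary sessions; exchange counts
N(105, 15²) clipped to [40, 135] and word/speech rates chosen so the median
session runs ≈ 47 minutes (the generated median falls in the 39–53 minute
interquartile band; extremes reach ≈ 25–77 minutes, slightly wider than the
13–69 reference range); decreasing negative-emotionality and past-oriented
language with increasing future-oriented and "we" language; therapist
negativity starting above the patient level with a slope that closes the
gap by the last quintile's midpoint (convergence); planted links
concentrated on rate-of-speech features with a negative sign
(words-per-second → words-per-second, lag 0, c = −0.5, which gives a latent
partial correlation of |c|/√(1+c²) ≈ 0.45 before the exp transform and
differencing); signature offset sd 0.2, calibrated so the within-therapist
signature correlation sits near 0.4 (an ICC ≈ 0.4 regime); and a
diagnosis-linked shift of 0.4–0.5 latent units on four features without
timing intent. `null_config` zeroes every planted effect for type-I-error
suites.

What the generator does **not** emulate: real lexical semantics, topic
structure, disfluencies, overlapping speech, transcription noise, or
dictionary coverage effects. Passing recovery tests therefore demonstrates
that the pipeline's statistics detect the structures they target at
realistic sizes and noise levels — not that those structures are detectable
in any particular clinical corpus with any particular dictionary.

## Problem sizes in the test suite

The acceptance tests run, per suite: 200 null dyads (two generated
100-session null corpora) for FDR control; 30 single-dyad corpora at
T = 300 for link recovery; 60 seeded 3-variable VARs at T = 200 for
equivalence with an independently coded PC1+MCI reference; 25 planted and
12 null corpora at the 78 + 20 geometry (sessions shortened to ≈ 60
exchanges) for consistency recovery; 40 planted and 40 permuted
classification datasets at n = 88 with 200 split repeats; and two full
pipeline runs on a small corpus for byte-level determinism. Recovery
thresholds keep the target rates (e.g. ≥ 90% → ⌈0.9·n⌉ of n seeds) at these
sizes. Stochastic tests draw from fixed per-test seeds, so the suite is
deterministic.

## Known limitations

- The exchange alignment (patient turn then therapist turn) is one of
  several defensible utterance-series conventions; τ_max, the FDR family
  scope, and the ADF screening test are likewise package choices exposed in
  `ResponsivenessConfig` rather than field standards.
- PC-style parent selection retains spurious parents at roughly the
  `alpha_pc` rate; MCI's conditioning then controls, but does not
  eliminate, their effect on the link family.
- The built-in stand-in lexicons are intentionally tiny; analyses of real
  transcripts should load full dictionaries.
- Welch's t on correlation samples ignores the dependence among the 3003
  between-pairs (each session participates in 77 of them); the within/
  between comparison should be read as descriptive strength of evidence,
  as in the analyses it follows.
- The empirical-p convention (share of repeats with difference ≤ 0) is
  anti-conservative under the null; its recovery tests bound, rather than
  calibrate, that behavior.
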