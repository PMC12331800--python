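# Methods

## The task and the scientific question

The package models a two-alternative forced-choice (2AFC) magnitude
experiment on dot-array stimuli. Each display half is a rotated square
(area in abstract units; the half-display "void" is 32 units) that may
contain non-overlapping dots. A session has three blocks: *area-only*
(judge which square is larger; no dots), *number-only* (judge which side
has more dots; the constraining square is not drawn), and *area & number*
(an area judgement in which the comparison's dot count matches its area
ratio exactly, so dot density is identical on both sides). The standard is
always 12 units / 12 dots; comparison ratios are 9/12–16/12 excluding 1.
Dot counts stay in 9–16, above the subitizing range and below texture-like
densities.

The question the design discriminates: does vision estimate **number** and
area as independent primary dimensions (deriving density by division), or
**density** and area (deriving number by multiplication)? On
density-equated area & number trials a number-primary observer gains an
independent second cue and should improve toward the optimal-fusion bound;
a density-primary observer's derived number signal is a noisy copy of its
area signal and cannot help.

## Psychometric model

Choice probability follows a lapse-mixed Gaussian signal-detection model:

    P(choose comparison) = Φ((c − s) / σ) · .97 + .015,
    σ = sqrt((w s)² + (w c)²)

with `s`, `c` the standard and comparison magnitudes and `w` the Weber
fraction — each magnitude is perceived with zero-mean Gaussian noise whose
SD is proportional to its size. The lapse constants .97/.015 are fixed
model structure (a 3% stimulus-independent guessing mixture), not free
parameters: the single free parameter per participant × trial type is `w`.
Consequences used by the tests: P is 0.5 at c = s, bounded in
[.015, .985], strictly increasing in c, and invariant to rescaling
(s, c) → (ks, kc).

`w` is fitted by maximizing the Bernoulli likelihood with a bounded scalar
search on w ∈ [1e-4, 2] (tolerance 1e-8; an exhaustive grid is the
fallback if the optimizer reports failure). To keep the likelihood away
from the degenerate w → 0 solution for error-free participants, one
half-weight pseudo-trial (ratio 11/12, comparison chosen, weight 0.5) is
appended before fitting; it is implemented as an explicit weighted record
so its influence is traceable in the likelihood, and it adds 0.5 to the
effective trial count.

The cue-combination bound for two independent cues with Weber fractions
w_a and w_n is the inverse-variance fusion value
`(w_a⁻² + w_n⁻²)^(−1/2)`. It is computed per participant from that
participant's own area-only and number-only fits and only then aggregated;
combining aggregated fits is a different (wrong) quantity on heterogeneous
cohorts, and a regression test guards the distinction.

## Exclusion rules

* **Above chance.** A participant is retained only if their pooled testing
  accuracy (126 trials) beats 0.5 on a one-sided exact binomial test at
  α = .05. Pooling across the three blocks (rather than per block) is the
  package's choice: the exclusion is per participant, and the pooled test
  is the most powered test of "performed above chance at all".
* **Outliers.** Per trial type, a fitted w is an outlier when it is
  *strictly* more than 3× the trial-type median, computed once over all
  candidates that passed the above-chance filter (no iterative
  re-medianing). Observation scope drops the single fit; participant scope
  drops every fit of the offending participant. Default scope is
  observation-level for exp1-style analyses and participant-level for
  exp2-style; both are exposed.

## Brightness and the bright-congruent selection

Stimulus colors are analytic constants: exp1 uses a mid-blue square
(RGB .25/.25/.50, i.e. HSV (2/3, 1/2, 1/2)) in a mid-grey void; exp2 uses
a mid-grey square on a lightness-matched blue-green background
(38/255, 132/255, 212/255), with a plain mid-grey background for
number-only blocks. Exp1 dots are white or black with a white percentage
drawn uniformly in [20%, 80%] per side; exp2 dots are white discs inside
black rings of equal area, so each dot's mean luminance is 0.5 regardless
of model.

Mean luminance is computed analytically as the area-weighted mixture of
void, square and dot regions (dot positions never matter for an area
average). The default luminance scale is the mean of the RGB channels;
CIELAB L*/100 is available as an alternative. The default averaging region
is the whole display side (void included); square-only averaging is
exposed as a config option because either reading of "average brightness"
is defensible. A brute-force rasterization oracle in the test suite
confirms the analytic values to < 0.005.

*Bright-congruent* area & number trials are exactly those testing trials
whose larger-area side also has the higher mean luminance. This is a
luminance criterion, not a white-dot-count criterion: a side can hold more
white dots yet be darker (lower white percentage; a larger square also
displaces brighter void under the exp1 palette), and the tests construct
such a trial explicitly.

## Synthetic observers

Every perceived magnitude m is m(1 + w z), z ~ N(0, 1). The architecture
flag decides which magnitudes are primary:

* **number-primary**: area and number are perceived independently
  (w_area, w_number).
* **density-primary**: area and density are perceived independently
  (w_area, w_density); each side's number estimate is the product of that
  side's density and area estimates, which makes the derived number signal
  strongly correlated with the area signal (the correlation is > 0.5 at
  study-scale parameters, and near 0 for number-primary — the
  "photocopy" mechanism, tested directly).

Decision variables are inverse-variance-weighted evidence sums: area tasks
use dA/var(dA), number tasks dN/var(dN), and area & number their sum; the
density-primary fusion weighs its derived number channel by its actual
reliability (effective Weber sqrt(w_area² + w_density²)). A lapse
parameter (default .03, mirroring the fitted model's fixed mixture) turns
a random subset of trials into coin flips. An optional `brightness_weight`
adds evidence proportional to the luminance difference, modeling the
incidental brightness influence; it defaults to 0.

Cohort defaults are chosen to sit at the scale of the study's descriptive
statistics: template w_area = .074 and w_number = .13 (the reported
area-only and number-only central values), and w_density = .105, chosen so
the density-primary observer's asymptotic area & number Weber fraction
(.078, measured by fitting 200k simulated trials) reproduces the reported
area & number level against .074 for area alone — i.e. the generative
"no improvement, slightly worse" penalty matches the published gap rather
than being exaggerated for convenience. Between-participant heterogeneity
is log-normal on each Weber fraction (keeping them positive) with log-SD
0.3, which together with 42-trial fit noise reproduces the reported
between-participant SD scale (~.03 around .074).

The default cohort path samples magnitudes, color composition and analytic
luminance without placing dots (positions never enter the decision model),
which keeps 100-cohort sweeps cheap; `full_stimuli=True` exercises the
complete geometric generator, including re-use of area-only squares by
area & number trials. What the generator does **not** emulate: sequential
and learning effects, reaction times, feedback-driven strategy change,
non-Gaussian or log-encoded noise, and any spatial effects of dot
arrangement. Passing tests therefore show that the analysis chain
discriminates the two architectures under Weber-noise observers at the
study's scale — not that real observers contain no further structure.

## Inference

One-sided paired t-tests orient the differences so the hypothesized
direction is positive; p is the upper tail and Cohen's d = t/√n (the
paired-design identity d = mean/SD of differences). All-zero differences
return the degenerate no-evidence result (t = 0, p = .5, d = 0); constant
nonzero differences raise, since the statistic is undefined.

The JZS Bayes factor for a paired design places a Cauchy(0, r) prior
(default r = .707) on the standardized effect δ and integrates the
noncentral-t likelihood over it; one-sided alternatives truncate the prior
to the hypothesized half-line and renormalize — the dominant convention in
Bayes-factor software, and the one that reproduces the published values.
Quadrature is adaptive with relative tolerance 1e-10 over the infinite
half-line; deep prior-tail evaluations where the noncentral-t density
underflows (and scipy's backend can overflow internally) are treated as
zero, which is exact to well below the quadrature tolerance. An
independent Monte-Carlo prior-sampling oracle (averaging the
noncentral-t likelihood over half-Cauchy draws) cross-checks the
quadrature to < 1% in the tests.

The sequential design evaluates the running Bayes factor at n_start = 30
and after each batch of 5 (never mid-batch), stopping at BF10 > 20
(decision "effect"), BF01 > 20 ("null"), or a cap ("undecided-at-cap").
A scaled-down operating-characteristic simulation in the tests confirms
that false "effect" decisions under a true null are rare.

## Numerical and degenerate-input choices

* Dot area defaults to 0.05 units² so 16 non-overlapping dots always fit
  the smallest (9-unit) constraining square; discs must lie fully inside
  the square (strictly stronger than requiring centers inside, and it
  makes the analytic luminance exact); placement is rejection sampling
  with at most 10,000 attempts before an explicit error.
* Ties in the decision variable (probability zero under the noise model)
  are resolved by a fair coin.
* Report JSON is emitted with sorted keys so identical inputs give
  byte-identical reports.
* Choice tables are validated on read: ratio set membership (never
  12/12), condition labels, and consistency of the comparison magnitude
  with the stated ratio, with offending row numbers in the error.

## Problem sizes used by the test suite

Cohort-level checks run 50 replicates per architecture at n = 82
participants (the study-scale sample) through the full chain; parameter
recovery uses 200 simulated 42-trial participants; oracle equivalences use
10⁶ draws (choice probability) and 10⁷ prior draws (Bayes factor). These
sizes keep the full suite around two minutes on one CPU while leaving the
statistical margins of every check at ≥ 2σ.

## Known limitations

* No bias/PSE or asymmetric-lapse parameters; the psychometric model is
  the one-parameter pre-registered form.
* Confidence intervals for d are not produced (the interval construction
  behind published psychophysics CIs varies and is not modeled).
* The density-primary closed-form choice probability is only available
  where channels are independent; correlated-channel cases are handled by
  simulation.
* The column-map CSV adapter defers entirely to the caller for foreign
  layouts; it does not guess column semantics.
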