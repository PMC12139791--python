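# Methods

`connshift` implements the analysis chain used to ask how a within-subject
drug manipulation (an active condition MA vs placebo PL, scanned on separate
days) shifts connectome-based network signatures, and it ships a synthetic
cohort generator so the whole chain is testable without any imaging data.
This note records the models, the defaults and why they were chosen, and the
boundaries of what a green test establishes.

## Functional connectivity and network strength

A run's connectome is the Fisher z-transformed Pearson correlation between
the time series of every pair of parcellation nodes, z = atanh(r). r is
clipped to ±(1 − 10⁻⁷) before the transform so degenerate |r| = 1 pairs stay
finite and averageable; nothing downstream is sensitive to the exact clip.
Nodes flagged as missing propagate NaN rows/columns and are never dropped
from the matrix shape, which keeps connectomes aligned with masks.

Network strength against a binary edge mask is the mean z over the mask's
upper-triangle edges, with NaN edges dropped and the usable-edge count
reported. A strength with zero usable edges is NaN — an explicit undefined
marker, never silently 0, because missing-node edge drops can empty a small
mask. Strength is linear in the connectome, which the tests exploit.

The attention signature is the difference score (high-attention strength −
low-attention strength); the same construction applies to the arousal and
valence mask pairs. The sustained-attention CPM's published linear model
(coefficient and intercept mapping the difference score to a predicted task
sensitivity) is a configuration input: its values live in the external mask
repository and are deliberately not hard-coded; the defaults (1, 0) are
identity placeholders.

## Quality control and pairing

Run-level exclusion mirrors the study's motion rules with strict
inequalities (the rules are phrased as "exceeding"/"greater than"/"more
than"): maximum censored displacement > 3 mm, average censored motion
> 0.15 mm, or > 50% of frames censored; a run exactly at a bound is kept.
Runs with missing data are excluded with a `missing_data` reason. Whether
missing nodes exclude the whole run (default) or only NaN-out their edges is
configurable (`strict_nodes`), since the source description is ambiguous on
this point. The two reward-task runs are averaged elementwise when both
survive QC and passed through singly otherwise; subjects enter a condition
contrast only with a usable run of that type in both conditions.

## Paired inference

Condition contrasts are one-sample t-tests on within-subject difference
scores (MA − PL), two-tailed, with Cohen's d = mean(diff)/sd(diff) — the
paired-design convention consistent with the effect sizes the study reports
(d ≈ t/√n). One deliberate convention: identical conditions (all differences
exactly zero) return t = 0, p = 1 rather than an error; a *constant nonzero*
difference still raises, since no finite t exists.

The canonical-network contrast computes each subject's 8×8 grid of mean
connectivity within and between eight canonical resting-state networks
(unique unordered node pairs, self-pairs excluded, symmetric by
construction), takes cellwise paired t-tests, and Bonferroni-corrects at
α = 0.05/64 over the full 8×8 family *including* symmetric duplicates —
faithful to the published correction even though only 36 cells are unique.
Subjects with an undefined cell are dropped from that cell only.

Cross-run consistency and brain–behavior coupling are Pearson correlations
of per-subject change scores across run types, or against the change in task
sensitivity.

## Paired leave-one-subject-out classification

A linear soft-margin SVM (C = 1 by default; Fisher-z edges share a scale, so
no feature standardization) classifies condition from upper-triangle edge
vectors. Cross-validation is leave-one-*subject*-out: both of a subject's
scans are held out together (the single scan, if only one survived QC), so
subject identity never leaks across the split; accuracy pools over all
held-out scans. Edges NaN in any scan are dropped globally so every fold
sees the same feature space.

Per-fold primal weight vectors are averaged as-is (no sign alignment — the
binary label set is fixed, so fold weights share an orientation) and
mirrored into a symmetric node×node map. Weights are oriented so a positive
weight always marks an edge *stronger under MA*; this matters because the
underlying solver orients its decision function by label sort order, which
would otherwise flip the convention. Top-weight edges are selected either by
absolute cutoffs (the published operative rule) or by a percentile rule
(floor(q% · finite edges) per side, ties broken by edge order); the
published "top 2.5%" phrasing is arithmetically inconsistent with its own
printed counts (0.025 × 35,778 ≈ 894, not 135/168), so both rules are
exposed and neither is guessed to be the intent.

Significance comes from a permutation null that flips each subject's
MA/PL label pair independently with probability ½ — the exchangeability
group of the paired design — and reruns the full cross-validation; a global
label reshuffle is available as an option. The p-value is the add-one
estimator (1 + #{null ≥ observed}) / (1 + n_perm), never exactly zero. The
permutation loop runs on a precomputed linear Gram matrix, which is
mathematically identical to the linear kernel on features.

**A known property, not a defect:** accuracy is a discrete statistic, so
null accuracies tie with the observed one with non-trivial probability at
desk scale (tens of scans); the add-one estimator then counts ties and the
permutation p is slightly conservative (super-uniform). The calibration test
sizes its cohorts (15 subjects) so a two-sided uniformity check still
passes; at realistic cohort sizes (~150 scans) the tie mass is negligible.

## Edge-set overlap

Whether two networks share more edges than chance: with M possible edges,
network sizes K and n, the overlap X is Hypergeometric(M, K, n). The test
reports the upper tail P(X ≥ x) = 1 − CDF(x − 1), computed via a log-stable
survival function. The source describes its MATLAB call as 1 − hygecdf(x,…),
which literally is P(X > x) — but recomputing the published worked examples
shows they all follow the ≥ x convention, so ≥ x is the default and the
literal convention is available by flag. Reported tables round half-up to
3 decimals to mirror printed conventions.

## Task-performance scoring

The sustained-attention task is go/no-go (90% go, 10% no-go, 750 trials per
session). Sensitivity is d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate), with
the standard 1/(2N) correction applied only to rates of exactly 0 or 1.
Response timing, gradual-onset window semantics and multiple presses are not
modeled: a trial is a binary respond/withhold outcome, which is sufficient
for d′ and every analysis in scope. The median split assigns at-median
subjects to the low group (a deterministic rule; the source does not state
its own).

## The synthetic world

The generator emulates the *statistical* structure the analysis assumes:

- **Base dependence.** A shared correlation matrix from a 3-factor model
  (loadings N(0, 0.35²), unit uniquenesses), giving the mild positive
  dependence typical of parcellated BOLD. One 7-minute run at TR 2 s is 210
  timepoints (the default).
- **Planted condition effect.** In the MA condition, correlations on the
  high-attention and positive-arousal mask edges are raised, and on the
  low-attention and negative-arousal edges lowered, by
  `effect_size × (g_s + h_{s,t})`, where g_s ~ N(1, subject_sd²) is shared
  across run types and h_{s,t} ~ N(0, run_effect_sd²) is run-type specific.
  The perturbed matrix is clipped to ±0.95 off-diagonal and repaired to the
  nearest positive-definite correlation matrix (eigenvalue clipping with
  diagonal rescaling) before sampling, so the effect lands exactly on the
  edges the pipeline scores.
- **Defaults and their calibration targets.** `effect_size = 0.15`,
  `subject_sd = run_effect_sd = 0.7`. These were fixed analytically before
  testing: the within-subject standardized effect on high-attention strength
  is ≈ 1/√(0.7² + 0.7²) ≈ 1.01 (slightly reduced by sampling noise), the
  regime the recovery tests assume; and the cross-run consistency of the
  drug-induced change is ≈ 0.7²/(0.7² + 0.7²) = 0.5, inside the 0.44–0.54
  band the study reports. The subject-heterogeneity ceiling on paired
  classification accuracy is P(g + h > 0) = Φ(1/0.99) ≈ 0.84 — the same
  regime as the published accuracy; the classifier power test uses
  `effect_size = 0.25` ("moderate"), which approaches that ceiling.
- **Masks.** Stand-in masks are sampled disjointly (configurable overlap)
  at the published edge counts on the full 268-node parcellation, scaled
  proportionally for smaller test parcellations. Mask sizes not printed
  anywhere (valence) use 500 edges per side.
- **Behavior.** Per-session task sensitivity: a subject baseline
  d₀ ~ N(2.0, 0.5²), a practice shift (+0.15 for post-orientation sessions),
  a condition shift (+0.25 under MA — reproducing the reported
  moderate behavioral improvement, d ≈ 0.4, at the reported session noise),
  session noise (SD 0.4), and an optional coupling term linking the
  behavioral change to the subject's network effect. The default coupling is
  0: the drug improves behavior and shifts networks, but the two changes are
  uncorrelated across subjects — the study's own (null) brain–behavior
  finding. Trials then come from the equal-variance signal-detection model.
- **QC fields are planted metadata, not derived from signals.** A
  configurable Bernoulli fraction of runs receives a randomly chosen failing
  motion metric.

What the generator does **not** emulate — and therefore what no green test
establishes anything about: hemodynamics and autocorrelated BOLD noise,
motion artifacts entangled with signal, spatial/anatomical structure of real
parcellations, non-Gaussian tails, site or session drifts, and any
relationship between the planted masks and real anatomy. Green tests
establish that the *pipeline* recovers what was planted and stays calibrated
under the null; they cannot validate the substantive neuroscience.

## Degenerate inputs and tie rules (summary)

| Situation | Behavior |
| --- | --- |
| r = ±1 in correlation | clipped to ±(1 − 10⁻⁷) before atanh |
| zero-variance valid node | error naming the node |
| QC metric exactly at bound | included (strict inequalities) |
| mask strength with no usable edges | NaN marker |
| paired t on identical conditions | t = 0, p = 1 |
| paired t on constant nonzero diffs | error |
| median-split tie at the median | low group |
| edge-selection ties at a percentile cutoff | stable edge-order tie-break |
| permutation p | add-one estimator, never 0 |
| hit/false-alarm rate 0 or 1 | 1/(2N) correction |

## Known limitations

- The generator's planted effect is exchangeable across edges within a
  mask; real drug effects are spatially structured.
- The nearest-PD repair slightly shrinks large planted shifts, so the
  realized edge-level effect is marginally smaller than `effect_size` at
  extreme multipliers.
- `select_edges` percentile counts use floor(), so tiny weight maps can
  select zero edges (a warning, not an error).
- The permutation test's desk-scale tie conservatism discussed above.
- The saCPM coefficient/intercept defaults are placeholders; predicted-d′
  analyses on real data must supply the published values.
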