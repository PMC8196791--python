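# Methods

## Model and rationale

A CGM record samples glucose nominally every 5 minutes. Over a fixed
window (24 h = 288 samples, 6 h = 72 samples) the times spent in the five
consensus glucose ranges (<54, 54–70, 70–180, 180–250, >250 mg/dL) sum to
the window length, so only the ratios between them are informative. All
statistics in this package therefore run in log-ratio coordinates:
centered log-ratios (clr) for geometry and biplots, and isometric
log-ratios (ilr) from a fixed sequential binary partition (SBP) for
clustering and discrimination. The SBP is chosen for clinical meaning,
not fitted: balance 1 = hypoglycemic vs other time, balance 2 = level 2
vs level 1 hypoglycemia, balance 3 = hyperglycemic vs normoglycemic time,
balance 4 = level 2 vs level 1 hyperglycemia. Balance j carries the
coefficient `sqrt(r·s/(r+s))` (r plus-parts, s minus-parts); natural
logarithms throughout. The basis rows are orthonormal zero-sum vectors,
so Euclidean distance on ilr coordinates equals the Aitchison distance —
the property that justifies k-means and Gaussian discriminants here.

The pipeline estimates three things per patient: (1) categories of 24-h
days and of 6-h periods (k-means on ilr coordinates, best of 25 random
restarts); (2) a linear discriminant that assigns a trailing 24-h
composition, at any anchor time, to one of the day categories; and (3)
per anchor time, an empirical row-stochastic matrix of the probability
that a day of category g is followed by a 6-h period of category h.
All three are strictly per-patient; categories of different patients are
not comparable and no pooling operation is provided.

## Windowing and validity

Windows are half-open `[start, start+duration)` so an anchor instant
belongs to the window it starts: consecutive same-anchor 24-h windows
tile the timeline without double counting. A sample is valid if present,
parseable and positive; no physiological plausibility filter is applied.
Validity requires every 6-h sub-block to hold at least `ceil(0.70 × 72) =
51` samples; the ceiling implements "at least 70%" on integer counts
(50/72 = 69.4% fails, 51/72 = 70.8% passes). Standalone 6-h windows are
held to the same rule on their single block. Timestamps are snapped to
the nearest 5-min grid slot; collisions keep the first sample and warn.

Missing time in a valid window is divided in equal shares among the
ranges with at least one observed sample. Equal shares (not proportional
ones) are used deliberately: proportional allocation preserves ratios and
would be a no-op after closure, whereas the equal-share rule encodes that
a missing sample could have come from any occupied range with equal
prior weight. Redistribution never creates time in a range with no
observed sample — such zeros are handled by the censoring model instead.

## Zeros

A zero minute-count means "less than one 5-min sample", so each zero cell
gets a detection limit of `fraction × 5 min` (default fraction 1.0,
configurable per part). The primary replacement is a log-ratio EM: rows
are mapped to additive log-ratio coordinates against a zero-free
reference part (the zero-free column with the largest geometric mean);
a zero cell becomes a coordinate censored below `ln(dl/x_ref)`. The
E-step replaces each censored coordinate by its truncated-normal
conditional expectation given the observed coordinates and accumulates
the truncation variance; the M-step re-estimates the mean and covariance
(maximum-likelihood scaling). This is exact EM for rows with at most one
censored cell; with several censored cells in a row the cellwise
truncation ignores their residual correlation, a standard and documented
approximation. Convergence is declared when no imputed log value moves
by more than 1e-8 (cap 200 iterations, warned). Imputed values are
strictly below their detection limits; non-zero parts are rescaled by a
common factor so each row's closure constant is preserved exactly, which
also preserves all ratios among non-zero parts. With fewer than D+1 rows
or no zero-free part the module falls back to multiplicative replacement
(`0.65 × dl` into each zero, non-zeros rescaled), logged. A part that is
zero in every row is unidentifiable and raises instead of guessing.

## Clustering and letters

K-means runs on ilr coordinates with `init="random"`, 25 restarts and a
fixed seed; results are invariant to the choice of orthonormal basis.
Empty clusters are handled by the underlying implementation's relocation
strategy. Internal validity uses Calinski–Harabasz, Dunn (single-linkage
inter-cluster distance over maximum diameter) and mean silhouette
(singletons contribute 0). `select_k` reports the table and deliberately
declares no winner: the number of categories is chosen jointly with the
clinical interpretability of the groups. Fitted clusters are mapped to
letters (V–Z for days, A–D for periods) by sorting group centers on the
first balance in decreasing order, so the most hypoglycemia-dominated
group always receives the first letter; the letters are a reporting
convention, not a property of the optimizer.

Group profiles report each group's compositional center (closed
geometric means, in minutes) and the log-ratio of each part against the
overall center. Because the clr of the closed center equals the mean of
row clrs, `exp(log_ratio) × overall_part` reconstructs the group part
exactly; `exp(4.12) ≈ 61` on a 0.6-min part is read as "about 61 times
the average, ≈ 37 min".

## Discriminant and transitions

The discriminant is a Gaussian equal-covariance model on ilr
coordinates: class means, pooled within-class covariance (ridge
`1e-8·trace/p·I` added only if near-singular), priors empirical by
default (uniform optional). Ties break to the lowest class label.
Accuracy is leave-one-out: rows whose removal would leave a singleton
class are skipped with a warning and excluded from the denominator. The
model is trained on 00:00–24:00 days only and applied to trailing 24-h
compositions at any anchor.

Transition probabilities are raw row-normalized counts (5 of 7 → 71.43%),
optionally Laplace-smoothed (off by default, matching the empirical
reading). Rows with no observations are reported as undefined, never as
zeros, and prediction from an undefined row raises.

## Clinical outcome metrics

Avg BG is the arithmetic mean and BGV the sample standard deviation of
the window's samples — BGV has no single standard definition, and the SD
convention is documented as this package's choice. LBGI/HBGI use the
mg/dL risk transform `f(BG) = 1.509((ln BG)^1.084 − 5.381)`, per-sample
risk `10 f²`, averaged over all samples with only negative-f (resp.
positive-f) samples contributing. Insulin/carbohydrate covariates are
outside the model; the report stage only aggregates glucose-derived
quantities.

## Synthetic data

A `PatientScenario` specifies archetype compositions per day category
and per 6-h category, an ilr noise scale, day-category frequencies, a
per-anchor transition kernel and an MCAR missingness rate. Samples are
archetypes perturbed by N(0, scale²) in ilr space (strictly positive by
construction); traces realize a composition by largest-remainder rounding
of minutes to 5-min sample counts and uniform draws inside each range's
glucose band, clipped to the CGM-realistic 40–400 mg/dL span. The default
scenario has four day types and four period types with ilr separations of
2.5–9.4 against noise scale 0.3 (≥ 5× regime, mimicking the strong
between-group contrasts reported for real patients), day frequencies
(0.2, 0.3, 0.3, 0.2), kernel rows with the moderately concentrated shape
seen in per-patient transition tables, such as (0.55, 0.20, 0.15, 0.10),
and 5% missingness.

In generated series the first 6-h block of each day is drawn from the
kernel given the previous day's category and the remaining 18 h from the
day's own archetype, so the transition structure is physically embedded;
this slightly contaminates each day's composition with its inherited
first block. Statistical recovery tests therefore use composition-level
pair sampling (`sample_pairs`), which matches the estimators' sampling
model exactly. What the synthetic data do **not** emulate: intra-day
autocorrelation of glucose, sensor drift and compression artifacts,
non-random missingness (device removal at night), and any insulin/meal
dynamics — so passing tests demonstrate correctness of the estimators
under the stated generative model, not clinical performance on real CGM.

## Problem sizes and numerical choices

Tests run planted-cluster recovery at 500 pairs, LOOCV nulls at n = 200,
kernel-recovery coverage at 500 draws per kernel row over 100 seeds
(per-cell ±0.05 band, ≥95% coverage; at 500 per row the worst-case
binomial SE is 0.022, giving ~97.5% theoretical coverage). The whole
suite completes in well under a minute. Closure tolerance is relative
1e-9; clr zero-sum and basis orthonormality hold to 1e-12; isometry of
clr/ilr distances to 1e-10. Degenerate inputs (all-zero compositions,
rank-deficient biplots, k > n, undefined transition rows, non-anchor
window starts) raise informative errors rather than returning silently.

## Known limitations

- The lrEM E-step is cellwise; rows with many censored cells use an
  approximate conditional truncation.
- The letter-assignment convention orders groups on the first balance
  only; two groups differing mainly in hyperglycemia balance could swap
  letters under small perturbations of their centers.
- The transition model is first-order and per-anchor; it has no notion of
  covariates, trends or higher-order history.
- `select_k` provides indices only; choosing k remains a human decision.
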