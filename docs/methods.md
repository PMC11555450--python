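# Methods

## The instrument

e-Frail-CH is an electronic frailty measure for hospitalized older adults
(>= 65 years) computed from routinely collected data at admission and at
discharge. It follows the cumulative-deficit tradition of the Edmonton
Frail Scale: eight dimensions are scored independently and summed.

| dimension | range | derivation |
|---|---|---|
| cognition | 0-2 | clustered indicator combinations (alertness, orientation, concentration, learning/ADL capacity) |
| general health | 0-2 | ICD-10 + CHOP code count at discharge: 1 -> 0, 2 -> 1, >2 -> 2 |
| functional independence | 0-2 | clustered combinations of upper/lower-body care and dressing |
| social support | 0-2 | marital status x residence (married at home -> 0; single/divorced at home -> 1; other -> 2) |
| medication | 0-1 | polypharmacy: >= 5 concurrent medications |
| mood | 0-1 | exhaustion or coded mood disorder |
| continence | 0-1 | urinary incontinence or a drainage device |
| self-reported performance | 0-1 | any of five mobility/fall-risk flags |

The total spans 0-12; a total >= 6 flags frailty and >= 9 severe frailty.
Both cutoffs are configuration: they were anchored by Functional
Independence Measure (FIM) bands (independence, FIM >= 108, anchors 6; the
dependent band, FIM 18-53, anchors 9) and other sites may recalibrate. A
ninth dimension, nutrition, is accepted in input but dropped by
`drop_sparse_dimensions` whenever its missingness exceeds 50% in either
phase, which in the source register it does by a wide margin (roughly 93%
missing at admission, 84% at discharge).

Missing indicators score as the worst level of their dimension. The
instrument is a conservative clinical alert, not a diagnosis: an
unobserved deficit should raise, not silence, the flag. The exception is
the two mood flags, where absence of a code is read as "no code", since
these are administrative code presences rather than assessments. One
consequence worth knowing: the published intermediate conditions for
cognition and functional independence are not monotone cell-by-cell
(cognition `(0,0,1,0)` scores 2 while the strictly worse `(0,0,1,1)`
scores 1). We implement the conditions as printed; the monotonicity
property is therefore asserted only for the nested-condition dimensions.

Two published condition strings are ambiguous and our formalizations are
isolated in `scoring.py` (`_COGNITION_RULES`, `_FUNCTIONAL_RULES`):
cognition discharge "alert + one mild impairment among the rest" is read
as exactly one indicator at level 1, the others 0; functional discharge
"one care indicator impaired (any degree), dressing intact" is read as
exactly one of the two care indicators in {1, 2}, the other 0, both
dressing indicators 0. Medication counts feed the score of their own phase.

## Two-step clustering

The category boundaries of the four clustered dimensions are derived with
a two-stage procedure over indicator combinations:

1. **Precluster.** A single sequential pass condenses records into
   mergeable sufficient-statistic summaries (counts per category;
   count/sum/sum-of-squares for continuous variables). A record joins its
   nearest precluster when the merge cost is within a threshold, else
   starts a new one; on overflow of `max_preclusters` the threshold grows
   by half and the pass repeats over the summaries. The default threshold
   0 makes preclusters exactly the distinct profiles — the right
   granularity for low-cardinality ordinal data.
2. **Agglomerate.** Standard greedy hierarchical merging of the
   preclusters under the log-likelihood distance
   `d(a,b) = xi_a + xi_b - xi_{a u b}`, with
   `xi_v = -N_v [ sum_cont 1/2 ln(s2_pooled + s2_v) + sum_cat E_v ]`
   (natural-log entropy `E_v`; the pooled-variance offset keeps constant
   clusters finite; categorical-only runs — the instrument's actual use —
   never need it). Ties break on the lowest id pair, so traces are
   deterministic. Missing values are excluded from a variable's entropy
   denominator, never imputed.
3. **Select k.** BIC(J) = `-2 sum_v xi_v + J (2 K_cont + sum_k (L_k - 1)) ln N`
   is evaluated at every cut of the trace. A fixed k (the usual mode here:
   3 levels for 0-2 dimensions, 2 for 0-1) is honored; otherwise the BIC
   minimizer wins, refined among candidates within 2% of the minimum by
   the largest jump in successive merge distances.
4. **Quality.** Reported as the mean silhouette under the same distance,
   computed on unique profiles with multiplicity weights (O(P^2) in the
   number of distinct profiles, not records). Raw values live in [-1, 1];
   reports clamp to [0, 1] for comparability with the published 0.5-0.8
   range. The published "divisive coefficient" has no printed formula —
   the procedure it names is in fact agglomerative, which is what we
   implement — so silhouette is our stand-in and cross-study comparisons
   of this number are qualitative only.

Clusters are ordered by mean indicator severity and assigned scores
0..k-1; the resulting rule table maps every observed combination to a
score, with unseen combinations falling to the worst score. Clustering is
run per phase (admission and discharge conditions differ in the source
instrument); nothing prevents running it on pooled data.

## Synthetic register generator

The source registry (a Swiss multisite acute-care hospital, 53,690
hospitalizations, 2015-2017) is private. `cohortgen` generates cohorts
with the structure the analysis assumes, and ships the published score
distributions (Table-3-style counts) plus demographic marginals as
fixtures so the desk-scale statistics are exactly recomputable.

Each episode has one latent frailty factor on the score scale,
`f_adm ~ N(4.55, 2.0)`, and `f_dis = f_adm + 1.33 * drift + N(0, 0.2)`.
Every dimension gets a propensity `p_d = clip(f/12 + eps_d, 0, 1)` with
`eps_d ~ N(0, 0.15)` shared across phases (the single-factor assumption is
ours — the inter-dimension correlation of the real register is unpublished
— and `dimension_noise_sd` exposes it). Binary dimensions emit flags with
`P(any flag) = p_d` exactly; the 3-level dimensions cut `p_d` at 1/3 and
2/3 and then emit a representative indicator combination of that category.
General health and social support derive from the admission latent and are
constant across phases, as in the source data (code counts are fixed at
discharge; civil status does not change within a stay). The FIM total is
`126 - 8 f_dis + N(0, 6)`, rounded and clipped to [18, 126]. Death
(default 4.92%) removes the discharge panel and FIM and is independent of
frailty unless `death_latent_coupling` (log-odds per latent point) is set.
All draws come from one seed through named substreams, so identical
parameters give byte-identical cohorts.

Calibration, done once and frozen: `latent_mean_admission = 4.55` and
`latent_sd = 2.0` place the scored admission mean/SD at 5.33/2.62, close
to the published 5.30/2.59; `DRIFT_GAIN = 1.33` converts a drift stated in
score points to the latent scale so the scored mean admission->discharge
difference equals the configured drift (recovery error <= 0.02 points at
drifts 0, 0.45 and 1.0 with n = 10,000). The default drift 0.45 points is
the published mean change. Age is a normal (78.4, 7.9) resampled to the
>= 65 inclusion bound; length of stay is lognormal with median 8 days;
nutrition fields are set missing at the published 92.7%/83.8% rates.

What the generator does *not* emulate: readmission structure (the source
register had no patient identifiers), realistic ICD-10/CHOP vocabularies
(only counts), informative missingness, within-stay assessment error, or
the exact Table-2 category percentages. Passing tests on generated data
therefore demonstrate the pipeline's correctness and internal calibration,
not the clinical validity of the instrument on any real register.

## Validation statistics

- Distribution summaries use count-weighted means and sample (n-1) SDs; at
  registry n the n vs n-1 distinction is invisible at 2 decimals.
- ROC curves call an episode test-positive when its score reaches the
  cutoff; the reference positive class defaults to the FIM-impaired side
  (<= 107 for the frail cutoff, <= 53 for the severe cutoff) and the
  direction is configurable. The AUC is trapezoidal, which equals
  tie-adjusted pair counting; the optimal cutoff maximizes Youden's J,
  lowest cutoff on ties.
- Paired analyses (t test, per-indicator Wilcoxon signed rank) restrict to
  survivors with both phases; died episodes have no discharge assessment.
  The Wilcoxon p is exact for n <= 25 without ties, else a normal
  approximation with continuity and tie corrections.
- Spearman correlations use midranks with the t-approximation p-value.
- The normality check is a Kolmogorov-Smirnov statistic against a normal
  with estimated parameters, with a seeded Monte-Carlo p-value (the
  estimated-parameter null invalidates the textbook KS tail). It is
  provided for completeness, not used as a gate: on ordinal 0-12 scores it
  is at best descriptive.

## Numerical and design choices

- Natural logarithms throughout the clustering criterion.
- Merge distances are clamped at 0 below 1e-9 (they are nonnegative in
  exact arithmetic).
- Exclusion precedence in `apply_inclusion` is age -> sociodemographics ->
  missingness, so reason counts are unambiguous; the 20%-missing rule
  pools both phases by default (`per_phase=True` is available; the source
  description does not say which was used). The health-data denominator is
  all indicator-panel fields plus code and medication counts; nutrition is
  outside it.
- Problem sizes in tests and the acceptance script (10,000-episode
  cohorts, 3 seeds for drift recovery) were chosen to keep Monte-Carlo
  standard errors near 0.01 score points, which is comfortably inside
  every tolerance asserted.

## Known limitations

- The silhouette-based quality coefficient is not the (undefined)
  published coefficient; values agree only qualitatively with the 0.5-0.8
  range.
- The published change statistic "t_60,651 = 0.45 (95% CI 0.44-0.48)"
  reads as a mean difference labelled t, with degrees of freedom exceeding
  the paired n; we report the mean difference with its CI and the
  conventional t statistic separately and do not reproduce that figure.
- Cluster-derived rule tables depend on the cohort they were fit to;
  shipping them between sites without refitting is deliberately not
  supported by default (the built-in published conditions are the stable
  surface).
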