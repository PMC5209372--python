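# Methods

`tomgrowth` analyzes non-linearities in cross-sectional Theory-of-Mind (ToM)
development: children aged 3–11 years are each tested once on a 0–110-point
instrument, and the questions of interest concern the *shape* of the
score-versus-age curve — a plateau near 56 months, a temporary regression
(dip) at 72–78 months, and the transition signatures (moving skewness,
variability and growth rate) that accompany them.  Because the analyses are
developed and validated on synthetic data, this note documents both the
analysis machinery and the generating model, and is explicit about what
passing tests do and do not show about real data.

## The score scale

The instrument yields a sum-score of 0–110 points, decomposable into five
sub-scores: emotion recognition (max 14), mental/physical distinction
(max 44), seeing-leads-to-knowing (max 3), desires (max 17) and beliefs
(max 32).  The points arise from 74 binary test questions plus 18
justification questions scored 0/1/2 (74 + 36 = 110).  The data model
enforces these ceilings, the sub-score/total consistency, the 36–143-month
age range, and an administrator id in 1–8.

## Loess smoothing and curve reading

The smoother is classical locally weighted regression: at each month of a
36–143 grid, a local polynomial (degree 2 by default) is fitted by weighted
least squares to the `span * N` nearest children, with tricube weights on
distance scaled by the neighbourhood radius.  The span is a fraction of the
sample — a 20% window for score curves, 30% for indicator curves — so the
window *in months* varies with local data density (about ±7 months around
the dip ages under the reference design, far wider above 8 years where the
design thins out).  No robustness iterations are applied.  Degree 2 is the
default because the developmental readings are second-derivative readings;
a locally linear fit estimates curvature too noisily.  Both the degree and
span are arguments.

Curve reading:

* **Inflection scan.** The curve is differentiated twice (central
  differences), the raw second derivative is itself Loess-smoothed with a
  30% span (double-differencing a scatter smooth on a monthly grid is
  noise-amplifying), and local extrema with prominence at least 10% of the
  maximum absolute smoothed second derivative are reported as "marked".
  Estimates within one smoothing bandwidth of either end of the grid are
  excluded from both the normalization and the search: local-polynomial
  derivative estimates are boundary-biased there, and on realistic samples
  the boundary zone otherwise contributes spurious "earliest" inflections.
* **Dip detection.** Every interior local minimum inside the search range
  (default 60–96 months) is paired with the highest preceding local
  maximum; the deepest pair wins.  The descriptor carries onset, trough,
  recovery (first age regaining the onset level; the grid end if never) and
  depth.

## Transition indicators

Moving skewness and moving SD slide a window of `window_frac * N`
age-sorted children (default 20%, step one child); the window's center age
is its median age.  Skewness is the adjusted Fisher–Pearson estimator, SD
uses `ddof=1`.  The growth rate is the first derivative of the smoothed
curve.  All three series are Loess-smoothed with a 30% span before peaks or
associations are read.  Series are compared after linear interpolation onto
a common monthly grid; both raw covariance and Pearson correlation are
reported, and the correlation is preferred wherever a single number is
needed, because the covariance of two series in different units is not
comparable across implementations.

## Monte-Carlo tests against a monotone-growth null

The null hypothesis holds that the true mean curve never decreases and any
apparent dip is sampling noise.  The null model is fitted from the data:

* monotone mean — isotonic regression (pool-adjacent-violators) of score on
  age, evaluated on the monthly grid, lightly smoothed (moving average,
  width 3 grid steps) and re-projected onto the monotone cone;
* residual SD — a Loess fit (30% span, degree 1) of absolute residuals,
  scaled by `sqrt(pi/2)` (the normal-consistency factor for mean absolute
  deviation) and floored at 1 point.

Null cohorts redraw each child's score as
`clamp(round(mean(age) + Normal(0, sd(age))), 0, 110)` on the observed
ages.  Two statistics are scanned over windows of several lengths anywhere
along the age range, because neither the dip's location nor its duration is
assumed known: the **dip depth** (largest drop from any grid age to the
minimum within the following window) and the **most negative slope** over
intervals of each length.  Both equal their brute-force double-loop
definitions exactly (tested).  P-values use the add-one convention
`(1 + #{null >= observed}) / (1 + n_reps)`, reported per window length plus
a family-wise value for the max-over-windows statistic.  Under cohorts
drawn from their own fitted null the per-window p-values are uniform
(parametric-bootstrap calibration, KS-tested); the clamping at 0/110
introduces no measurable bias away from the clamps.

Administrator robustness repeats the test once per left-out administrator.
A planted "anomalous administrator" — one whose children inside a chosen
age window are deflated by a fixed number of points — serves as the
positive control: the artifact dip is significant on the full data and
loses significance exactly when that administrator is removed.

The gender-lead test asks whether a girls' dip at least as deep as
observed, with its trough up to 3 months before (but not after) the boys'
trough, is explicable under the girls' monotone null.  If the observed
girls' trough does not actually lead the boys' trough, the pattern is
absent and the test reports p = 1.  Trough locations of single-gender
subsamples (~160 children) carry ±3–4 months of sampling noise, so
planted-lead validation uses pooled replicates.

## The growth model

The dynamic-systems model is a van Geert-style connected-growers system.
The ToM level `L` grows logistically; two latent supporters `A` and `B`
(executive-function-like resources) emerge as logistic rises from a 1% seed
at 56 and 72 months.  Couplings, per internal Euler step of 0.25 months
(supporters advanced first):

    L <- L + dt * [ L * (r + s_A*A + s_B*B) * (1 - L / K_eff)
                    + (c_dA * dA/dt + c_dB * dB/dt) * S ]
    K_eff = K * (kappa_0 + kappa_A * C_A + kappa_B * C_B)

* **Support** (`s_A`, `s_B`): supporter levels raise the effective growth
  rate.
* **Capacity staging**: the momentary ceiling is unlocked by the
  supporters' *consolidated* levels `C_A`, `C_B` — the same logistic but at
  a slower consolidation rate (and, for B, after a lag): newly emerged
  resources take months to translate into testable ability.  This is what
  produces a plateau (growth stalls at the current tier until the next
  supporter consolidates) and the gentle, years-long final approach toward
  the ceiling.
* **Competition** (`c_dA`, `c_dB`): while a supporter's level is *changing*
  it drains expressed ability directly, at `c * dX/dt * S` points per month
  (`S` = 14 points per unit change).  The drain is deliberately not
  multiplied by the logistic saturation factor: reorganization costs apply
  even when the child sits at their momentary ceiling.  Whether the drain
  is *visible* as a dip depends on how fast the gender's growth rate
  refills it — with the default parameters the same mechanism yields a
  marked dip in boys and a somewhat shallower one in girls, and the plateau
  is detectable in girls but concealed in boys, purely through the
  difference in `r`.

Per-gender parameters (defaults): girls `r=0.15, s_A=0.33, s_B=0.24,
c_dA=0, c_dB=-3.20`; boys `r=0.10, s_A=0.10, s_B=0.16, c_dA=0,
c_dB=-2.50`; shared structural constants `K=110`, `L0=44` points at 36
months, `kappa_0=0.60, kappa_A=0.10, kappa_B=0.24`, `S=14`, supporter rates
1.0/month, consolidation 1.0/month for A and 0.2/month with a 14-month lag
for B.  With all couplings and capacity gains zero the integrator reduces
to a plain logistic and matches the closed form to <1% at the default step;
successive step halvings converge first-order.  Fitting to a smoothed curve
minimizes mean squared error on the 36–120-month grid by Nelder–Mead with
seeded perturbed restarts, supporter onsets held fixed; on self-generated
targets the fit recovers `r` within ±0.02 and `c_dB` within ±0.5 from ±20%
perturbed starts.

Open choices resolved here: the paper family this model belongs to leaves
the exact update equation unspecified, and a pure
rate-modulation-with-single-ceiling form cannot produce an intermediate
plateau (support raises the rate, not the ceiling) nor an at-capacity dip
(a saturation-multiplied competition term vanishes exactly when the grower
sits at its ceiling); the capacity-staging and direct-drain forms above are
therefore the model of this package.  Rates are per month; `c_dA` defaults
to 0 but remains a free parameter in fitting.

## The synthetic cohort generator

The generator emulates the reference study design: 324 children (167 boys,
157 girls) in seven age bins — 3, 4, 5, 6, 7, 8–9 and 10–11 years, with
bin-by-gender counts fixed exactly and month-of-age uniform within each
bin (the true within-year distribution is unreported; uniform is an
assumption).  Each child's expected score is their gender's model
trajectory evaluated at `age + tau`, with a personal transition-timing
shift `tau ~ Normal(0, 3)` months, plus a stable person-level offset
(`Normal(0, 4)` points) and age-constant residual noise (`Normal(0, 5)`
points), rounded and clamped to 0–110.  The single time-shift device
produces the cross-sectional transition signatures (moving-SD peaks at the
spurts, skewness sign change across them) without scripting them.  The
timing spread is kept at 3 months because the cross-sectional dip is a
population-mean feature: convolving the trajectory with a wider timing
kernel (6 months, say) erases the dip entirely before any smoothing is
applied, after which no smoother could recover it.

Sub-scores are allocated deterministically from the total by
largest-remainder apportionment over ceiling-proportional weights, with an
age-dependent tilt (shaped like supporter B's emergence change) that
reduces each sub-score's share near the dip in proportion to a per-score
steepness constant — beliefs steepest, the 3-point seeing-knowing scale
untilted — so every rescaled sub-score curve dips near the same ages.
Administrators are assigned by dealing age-sorted blocks of 4 children
round-robin over 8 ids, so each administrator spans the full age range and
leave-one-out retains the dip; a config switch plants the anomalous
administrator described above.

Calibration: the structural constants were fixed, once, against the study
conditions the source analysis states — girls'/boys' mean sum-scores 71.71
and 68.73, the dip deepest at 78 months, the earliest marked inflection at
56 months, Monte-Carlo dip significance between 0.01 and 0.05, and
significance retained on every administrator-reduced subset.  Measured over
20 generator replicates: girls' median mean 72.3–72.5, boys' 68.0–68.4,
median trough 78, median earliest inflection 57–58, median dip-test min-p
≈ 0.01.  Within-gender overall SDs come out near 17–19 points against the
reported ≈ 20.8/20.4 — the generator is slightly tighter than the real
data.

What the generator does *not* emulate: item-level responses, language
covariates, administrator bias beyond the planted control, floor/ceiling
response styles, and any within-child longitudinal dependence (the data
are one row per child by design).  Passing tests therefore show that the
analysis machinery recovers planted effects of realistic size under the
study's design and noise level — not that the developmental claims hold in
real data.

Two further realism limits are known.  First, the generated cohorts carry
a late growth-rate peak (the slow final capacity release around 96–124
months) together with ceiling-compressed, negatively skewed scores at the
oldest ages, so the skewness/growth-rate correlation of *default* cohorts
is not reliably positive; the two-step transition simulation below is the
appropriate object for that analysis.  Second, with symmetric timing
heterogeneity the girls'/boys' dips end up of similar depth; the
boys-more-marked asymmetry is present in the noise-free trajectories but
modest in sampled cohorts.

## The two-step transition population simulation

A separate demonstration population implements the classic two-step growth
process: each of 10,000 children climbs two logistic step episodes
(+30 and +35 points, rise rate 0.2/month) centered on personal transition
ages around 64 and 86 months, with residual SD 7.  The timing shifts are
**left-skewed** (`tau = s - Exponential(s)`, scale 6 months): a minority of
rapid developers runs ahead while nobody lags far behind.  This choice is
deliberate: with *symmetric* timing the cross-sectional skewness is
antisymmetric around each step (the third-cumulant expansion of
`L(t - tau)` gives skew ∝ `L'^2 L''`), so it is nearly orthogonal to the
growth-rate bumps; the left-skewed shifts contribute a `|E tau^3| L'^3`
term that peaks with — slightly before — the growth rate, which is what a
high skew/growth-rate covariance requires.  Symmetric timing remains
available (`timing="normal"`) and then shows the positive-before /
negative-after sign flip instead.  On the defaults, smoothed skewness and
growth rate each show exactly two peaks, skewness peaks lead, and their
correlation is ≈ 0.55–0.65 (window fraction 0.06 at this population size).

## Numerical and procedural choices

* Monthly evaluation grid 36–143; integrator step 0.25 months.
* Nearest-neighbour ties at the window boundary are all included; an
  all-zero tricube row (degenerate neighbourhoods) falls back to uniform
  weights, and singular local systems fall back to least squares.
* Sub-score allocation uses stable largest-remainder rounding; ties broken
  by fractional part order.
* All randomness flows through `numpy` Generators seeded per stage;
  pipeline stages derive named seeds from one master seed.  Identical
  configuration and seed reproduce byte-identical artifacts.
* Problem sizes used by the shipped checks: 20 generator replicates for
  trough/inflection/mean medians, 10 replicates × 200 null draws for the
  dip test, 100 × 99 draws for calibration, 5 replicates of the
  10,000-child transition population.  These sizes put the medians'
  sampling error well inside the tolerances they are compared against.

## Known limitations

* The Loess implementation is deliberately plain (no robustness
  iterations, no local bandwidth adaptation); outlier-heavy data would
  need the robust variant.
* The monotone null is fitted to the same data it is tested on; the
  resulting p-values are (mildly conservatively) calibrated by the
  parametric bootstrap, as the shipped calibration check shows, but they
  are not exact finite-sample p-values.
* Trough locations from single-gender subsamples are noisy (±3–4 months);
  gender-timing comparisons should pool replicates or bootstrap.
* The growth model's structural constants (capacity fractions,
  consolidation rates, drain scale) are identifiable only jointly with the
  per-gender parameters; `fit_to_curve` treats them as fixed and fits the
  per-gender parameters.
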