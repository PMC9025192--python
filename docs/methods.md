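# Methods

## Model

Tumor volume $V(t)$ (cm³; proportional to cell number at constant cellular
density) follows a two-parameter macroscopic growth law.

**Gompertz (GL).**  $(1/V)\,dV/dt = k \ln(V_\infty/V)$, solved by
$\ln V(t) = \ln V_\infty + \ln(V_0/V_\infty)e^{-kt}$.  $k$ (day⁻¹) sets the
approach rate, $V_\infty$ is the carrying capacity (CC).  The solution has
the semigroup property: restarting from $V(t_1)$ with the same $(V_\infty,k)$
reproduces the original trajectory.  That property is the whole
treatment-response formalism: therapy is modelled as a change of the CC, so
for $t>t^*$ (end of treatment) the law restarts from $V(t^*)$ with the
dose-dependent $V_\infty(d)$, giving
$V(t)/V(t^*)=\exp\{\ln[V_\infty(d)/V(t^*)](1-e^{-k(t-t^*)})\}$.
No differential equation for the CC itself is assumed — the approach is
deliberately model-independent about *how* radiation and drugs reshape the
microenvironment.

**Logistic (LL).**  Implemented as the exponential relaxation
$V(t)=V_\infty+(V_0-V_\infty)e^{-\lambda t}$, which satisfies $V(0)=V_0$,
$V(\infty)=V_\infty$, and reduces *exactly* to $V_0e^{-\lambda t}$ as
$V_\infty\to 0$.  This is the form under which the complete-response (CR)
regime of both laws coincides ($\rho=\lambda$ for LL, $\rho=k|\ln(V_\infty/V_0)|$
for GL), which is the property the cross-law robustness argument rests on;
the sigmoidal logistic does not have an exponential small-CC limit and is
not what the CR fits behave like.

**Radiosensitivity.**  Cell kill per fractionated course is summarised by
the linear-quadratic model $-\ln S = n(\alpha d + \beta d^2)$; it is kept as
a standalone formula (the CC inversion does not assume any LQ-to-CC link).

Units are fixed: days, cm³ (or dimensionless ratios), rates per day.
Non-positive volumes, rates or CCs are hard errors everywhere — never
clamped.

## Fitting

Loss: unweighted least squares in **log volume** (measurement error on
volumes is multiplicative, and the GL is linear in $\ln V$ versus
$e^{-kt}$).  By default $V_0$ is fixed to the first observation, the right
choice for ratio series whose day-0 entry *defines* the normalization and is
therefore exact.  For absolute series (patient GTV), every point carries the
same multiplicative error, so the recommended setting is `fix_v0=False`:
pinning $V_0$ to a noisy measurement injects an offset the model cannot
absorb and measurably degrades parameter recovery.

Optimization is a deterministic multi-start (5 log-spaced CC-ratio starts ×
3 rate starts, plus a closed-form seed for 3-point series on a
$(0,\tau,2\tau)$ grid) of bounded nonlinear least squares; no RNG is used in
fitting.  Convergence failure of all starts raises with per-start
diagnostics.

**Identifiability.**  Strongly regressing series that look exponential
constrain only the composite rate, not $(V_\infty/V_0, k)$ separately.  The
fitter profiles the objective over $b=\ln(V_\infty/V_0)$ on a grid reaching
$|b|=16$ ($V_\infty/V_0\approx 10^{-7}$, matching the smallest CC ratios
reported for CR patients) and classifies the fit as `bound` when the profile
value at the grid floor is within the flatness threshold of the minimum:
$g(\text{floor}) \le g_{\min}(1+\eta)$ with $\eta = 4/(n-p)$ by default.
The threshold scales with the residual degrees of freedom because SSE
differences along a degenerate ridge fluctuate at order $\sigma^2\sqrt{n}$;
a fixed tiny threshold would classify noisy exponential series as point
estimates essentially at random.  $\eta=4/(n-p)$ corresponds to a ≈2σ
profile-likelihood criterion; ties go to `bound` (conservative).

A `bound` result reports:

* one-sided limits for $V_\infty/V_0$ and the rate, taken where the profile
  crosses the flatness contour;
* a point estimate of the **composite rate** — the quantity the data
  actually identify — computed as the log-linear regression slope of
  $\ln V$ on $t$ (through the fixed origin when $V_0$ is fixed).  On a
  degenerate ridge the product $k|b|$ varies along the ridge, so its value
  at any particular ridge point would be arbitrary; the exponential-rate
  estimate is deterministic and exact for exponential data;
* `params` holding the constrained optimum on the admissible ridge — the
  best in-sample curve, which is what forecasts extrapolate (flagged as
  exponential-regime extrapolation).

Goodness of fit is a reduced $\chi^2$ with relative measurement error
`sigma_rel` (default 0.10, the declared uncertainty of the xenograft ratio
table; override in config).

**Two-point closed form.**  For ratios $r_1, r_2$ at $(t_1, 2t_1)$ with
$V_0=1$: $x=\ln r_2/\ln r_1 - 1$, $k=-\ln x/t_1$,
$\ln V_\infty = \ln r_1/(1-x)$; no Gompertz exists unless
$\ln r_2/\ln r_1\in(1,2)$.  Two of the four untreated xenograft lines (L4,
L1) violate this (super-exponential measured growth), which is why their
least-squares fits are growth-side degenerate and carry bounds rather than
a parameter pair.

## Carrying-capacity inversion

$\ln[V_\infty(d)/V(t^*)] = \ln(\text{ratio})/(1-e^{-k\,\Delta t})$, the exact
inverse of the restart formula (round trip at 1e-12).  $k$ is held at the
untreated line's fitted value for every dose of that line: the observed
volume variations are moderate and the CC enters only logarithmically, so a
shared $k$ is the working approximation (per-dose $k$ available for
sensitivity).  When the untreated fit is itself degenerate, the pipeline
uses the rate at the flatness contour — the largest rate consistent with the
untreated data; responder calls are unaffected since the sign of
$\ln(\text{ratio})$ is $k$-independent.  Multiple timepoints are combined by
geometric mean (multiplicative error model); the per-timepoint values and
their maximum pairwise spread (`consistency`) are always retained.  Dose-0
rows are never inverted — they define $k$.

A structural caveat surfaced by the built-in dataset: two inversions at
$\Delta t$ and $2\Delta t$ can agree for *some* $k$ only if
$\ln r_{2\Delta t}/\ln r_{\Delta t} \in (1,2)$; two of the eight treated
rows (L4-8Gy, L1-10Gy) violate this, so their 15- vs 30-day inversions
disagree by ≳25–45% for every possible $k$.  The package reports the spread
honestly rather than averaging it away; the responder classification — the
decision-relevant output — is consistent across timepoints for all rows.

## Forecasting

`forecast` fits on observations up to a cutoff day and extrapolates the
closed form; predictions are scale-free ratios $V(t)/V(0)$.  At least three
prefix points are required — with fewer one cannot even in principle
distinguish a saturating law from an exponential or a line.  Both parameters
are refit from the prefix by default; `fix_rate` pins $k$ so only the CC is
re-estimated.  No uncertainty bands are produced in core.
`minimum_prefix_study` maps forecast error against prefix size on synthetic
cohorts with known truth and reports the smallest prefix meeting an error
budget — by construction 3 points at zero noise.

## Synthetic cohorts

The generator emulates the two study designs the analysis targets:

* **patient**: 23 visits evenly spread over 28 days (near-daily imaging
  during a ~28-fraction course), initial volumes log-uniform 20–150 cm³.
  Archetypes: PR with $V_\infty/V_0$ log-uniform [0.2, 0.65] and $k$ uniform
  [0.03, 0.11]/day (the envelope of reported partial responders); CR with
  $\log_{10}(V_\infty/V_0)$ uniform [−9, −7] and identifiable composite rate
  uniform [0.04, 0.1]/day (reported complete responders have CC ratios below
  ~5×10⁻⁷ and composites in exactly this band), $k$ derived; NT growth with
  ratio uniform [2.0, 2.8], $k$ uniform [0.03, 0.08]/day.
* **xenograft**: normalized ratio tables on the {0, 15, 30}-day schedule —
  an untreated series grown from $V(t^*)=1$ plus one post-treatment series
  per dose from the CC-restart formula with `cc_dose_map` ratios.

Noise is multiplicative log-normal, default 5% per measurement (the stated
precision of the xenograft experiment; patient measurement error is not
quantified in the source studies, so the same figure is reused).  Day-0
entries of normalized series are exact.  Seeds are mandatory; generation is
byte-reproducible.

What the generator does **not** emulate: treatment-phase transients
(volume increase from undrained dead material early in a course), irregular
real-world visit schedules, autocorrelated segmentation error, and
inter-observer GTV variability.  Passing recovery tests therefore show the
estimation machinery is correct and calibrated under the stated error model,
not that real GTV series satisfy that model.

## Numerical notes and limitations

* Profile grid: $|b|\in\{0.01,0.05,0.1,0.2,\dots,16\}$ on the side of the
  best fit; inner rate optimization by vectorized golden section on
  $\ln k \in [\ln 10^{-5}, \ln 2]$ (64 iterations).
* The recovery studies in the test suite use 200-subject cohorts at the
  conditions above; the prefix-size study in the tests uses 20 subjects and
  a thinned cutoff ladder.  A quantitative caveat measured on those
  cohorts: with 23 visits, 5% noise and the PR parameter envelope, the
  Fisher information of the log-volume model puts the *best attainable*
  median relative error of the composite rate near 9%, and the achieved
  median is ~10–12% depending on the noise realisation — composite-rate
  recovery at these conditions is information-limited, not
  optimizer-limited.
* Forecast accuracy from 11-point prefixes of PR-like series is likewise at
  its information limit (~10% median error at day 28 under 5% noise).
* The CC-versus-dose output is descriptive; no parametric dose-response
  curve is fitted, and no link from the LQ survival model to the CC change
  is assumed.
* Between-subject pooling (mixed effects), Bayesian posteriors, explicit
  CC dynamics, and imaging-derived volume extraction are out of scope; each
  subject is fitted independently.
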