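# Methods

## The measurement model

A 96-well screening plate carries one control row and up to seven compound
rows. In the control row, wells 1–9 hold untreated cells (cell control) and
wells 10–12 hold medium without cells; their means $A_{cc}$ and $A_{cm}$
anchor the assay's 0% and 100% inhibition levels. Compound rows hold four
concentrations in triplicate, descending left to right. Percent inhibition
of proliferation in a treated well with absorbance $A_p$ is the affine
normalization

$$IP = 100\,\Bigl(1 - \frac{A_p - A_{cm}}{A_{cc} - A_{cm}}\Bigr).$$

$IP$ is exactly 0 at $A_{cc}$, exactly 100 at $A_{cm}$, invariant under any
common affine rescaling of all absorbances (gain or offset drift of the
reader), and strictly decreasing in $A_p$. It is deliberately **not
clamped**: $IP < 0$ (growth stimulation) and $IP > 100$ occur with real
data and clamping them would bias every downstream fit. Instead, triplicate
means at or beyond 0%/100% are flagged, and the linear estimator filters
individual points to the open interval (0, 100).

Control statistics require at least two usable cell-control wells, one
usable medium well, and $A_{cc} > A_{cm}$; otherwise the analysis aborts —
there is no meaningful inhibition scale without a positive assay window.
All standard deviations are sample SDs (n−1 denominator); the choice is
stated because spreadsheet conventions differ.

## The three estimators

**Two-point interpolation.** Triplicate mean inhibitions are scanned in
ascending dose order for the first adjacent pair bracketing 50%; the IC50
is the abscissa where the chord between the two points, drawn in
transformed coordinates, crosses (transformed) 50%. With the default
log10 dose axis and linear inhibition axis this is

$$IC_{50} = 10^{\;\log C_{lower} + \frac{50 - IP_{lower}}{IP_{higher} - IP_{lower}}\,(\log C_{higher} - \log C_{lower})}.$$

The method is only defined for absolute IC50, reports no confidence
interval, and refuses — returning a reasoned non-result rather than a
number — when (a) no adjacent pair brackets 50%, (b) a bracketing mean is
exactly 0% or 100%, or (c) a bracketing mean lies inside the exclusion band
around 50% (default 48–52%): interpolating across a near-zero gradient
amplifies noise without bound, and the honest answer is to repeat the assay
on a narrower dose range. When non-monotone means produce several brackets,
the pair at the lowest concentrations is used — the first crossing is the
pharmacologically conservative choice.

**Transformed linear regression.** Ordinary least squares through the
individual well points (not triplicate means) with $0 < IP < 100$, after
transforming the dose axis (log2, log5, log10 or linear) and the inhibition
axis (linear, probit, logit or log10 — probit/logit act on the proportion
$IP/100$). At least three usable points are required; a non-positive fitted
slope or a crossing outside the representable dose range refuses. The
absolute IC50 inverts the line at transformed 50%. A straight line has no
plateau, so for the relative IC50 the plateau is taken as the largest
triplicate mean inhibition in the row and the line is inverted at half that
value; this convention is a package decision where the underlying concept
is genuinely undefined, and it reduces to the absolute case as the observed
maximum approaches 100%. Goodness of fit is $r^2$ on the transformed scale.

**Hill (nonlinear) regression** — the default. The zero-baseline Hill
curve

$$IP(C) = \frac{I_{max}\,C^h}{C^h + K^h}$$

is fit to *all* usable individual points (the 0–100 filter does not apply)
by least squares. The zero lower asymptote is structural: by construction
of the normalization, untreated growth defines 0%, so a three-parameter
form suffices and makes the relative IC50 identically $K$. The absolute
IC50 solves $IP(C) = 50$:

$$C_{abs} = K\,\Bigl(\frac{50}{I_{max} - 50}\Bigr)^{1/h},$$

refused when $I_{max} \le 50$ (the curve never reaches the control-defined
half-effect). Goodness of fit is $R^2 = 1 - SS_{res}/SS_{tot}$, reported
absent when the points have zero spread ($SS_{tot}=0$, the model
unidentifiable).

### Optimization

Nelder–Mead simplex on $(I_{max}, \log h, \log K)$: the log
reparameterization imposes positivity on $h$ and $K$ without constraints,
and $I_{max}$ carries a quadratic penalty below zero. Starting values:
$I_{max}$ from the largest per-dose mean inhibition (clipped to [1, 150]),
$K$ at the dose whose mean is closest to half that, $h = 1$. Stopping at
simplex spread below 1e−8 in both parameters and objective (loose enough to
terminate, ~6 orders tighter than the 1e−4 recovery accuracy the tests
demand). If the simplex exhausts its iteration budget it is re-inflated
once at the current best point — a stalled simplex almost always recovers
from a fresh start there; if that fails too, up to three restarts perturb
the starting $K$ by ×0.5, ×2, ×0.25. Bootstrap refits reuse the base fit
as the starting point with a lighter stopping rule (1e−4), which is far
below the resolution of a percentile interval over a few hundred
replicates.

## Uncertainty

**Semi-parametric bootstrap.** Regression IC50s carry 95% CIs obtained by
residual resampling: fit once, form residuals against the fitted curve,
resample them with replacement, add them back onto the fitted values,
refit, and take the (2.5, 97.5) percentiles of the replicate IC50s
(B = 1000 by default; percentile chosen as the simplest member of the
standard family of bootstrap intervals). Residuals live on the scale the
model is actually fit on — transformed inhibition for the linear method,
raw percent inhibition for the Hill fit — so pseudo-responses always stay
in the model's domain. Resampling is global across doses: with three wells
per dose, per-dose stratification would resample from three values and
badly understate variability.

Raw residuals from a fitted model are too small: the $i$-th residual has
variance $(1 - h_{ii})\sigma^2$, with $h_{ii}$ the fit's leverage (from the
hat matrix of the design matrix for the linear method, or of the model
Jacobian at the optimum for the Hill fit). The resampling pool therefore
uses the standard modified residuals $e_i/\sqrt{1-h_{ii}}$, centered. At
microplate sample sizes this is not a refinement but a necessity: with
n = 12 and p = 3 raw residuals are 13% too small in scale on average, and
simulation shows the uncorrected intervals' coverage of the true
half-maximal concentration falls to ~0.84 at the package's reference noise
level, against ~0.87–0.88 with the correction (see the acceptance suite,
which measures coverage over 200 seeded plates). Even corrected, the
percentile interval at these sample sizes sits slightly below its nominal
95%: the empirical residual pool of 12 values carries substantial spread
noise of its own, and the common-mode error in the plate's control means —
which distorts all twelve inhibition values jointly — is invisible to
residual resampling. Interval constructions that repair this
(studentized, BCa) are deliberately out of scope.

Replicates whose refit fails or refuses are dropped and counted; if more
than 20% fail, the CI is reported absent with a warning rather than
pretending the remaining replicates represent the sampling distribution.
Resampling uses one seeded generator owned by the run — identical seed and
inputs give bit-identical intervals. Exact coverage of the percentile
interval at n = 12 with a 3-parameter nonlinear model is not 95%; the
residual scheme also conditions on the observed controls, whose own noise
(common-mode across the plate) is not propagated. Both limits are inherent
to the interval construction, not to its implementation.

**Aggregation across assays.** IC50s from repeated independent assays are
summarized by the geometric mean — IC50s are log-normally distributed, so
the arithmetic mean of logs is the natural location estimate — with a
Student-t 95% interval on the log scale, exponentiated. A single assay
yields a point estimate and no interval.

**Outlier screening.** Within a triplicate, a value is flagged when it
deviates from the triplicate mean by more than $k$ sample SDs (default
$k = 1$). With $n = 3$ the largest achievable deviation is
$(n-1)/\sqrt{n} = 2/\sqrt{3} \approx 1.155$ SDs, so any $k$ at or above
that bound can never flag anything — a property test pins this. Flags are
always recorded for the report; flagged wells are *excluded* from
computation only when the discard option is on, and it is off by default:
automatic discarding of real biological variation is rarely defensible.
Screening runs on absorbances; inhibition is an affine function of
absorbance, so the flags would be identical either way.

## The simulator

The simulator inverts the normalization: it draws a plate whose control row
sits at true levels $A_{cc} = 1.0$, $A_{cm} = 0.1$ and whose compound wells
sit at the absorbance corresponding to the true Hill inhibition at each
well's dose, then adds Gaussian absorbance noise (additive by default,
matching photometer behavior near mid-range OD; proportional noise is an
option) and, with a configurable probability, replaces a well by a gross
error uniform on $[0, 2A_{cc}]$ to exercise the outlier rule. Wells are
visited in fixed row-major order, so a seed fully determines the plate.

Reference conditions used throughout the tests: truth
$(I_{max}, h, K) = (80, 1, 10)$ on a ten-fold dilution series
1000/100/10/1 (dose units arbitrary; µg/ml in the examples). The series
deliberately reaches two decades above $K$: the upper plateau must be
delineated by the design, or $I_{max}$ — and with it $K$ — is poorly
identified regardless of estimator. Under these conditions the median
relative error of $\hat K$ at 3%-of-window noise is ~9% (the tests assert
< 10%), and this is information-limited, not an optimizer artifact: a
Levenberg–Marquardt oracle reproduces the same median error to three
decimals.

What the simulator does *not* emulate: edge effects, spatial drift,
position-dependent pipetting bias, heteroscedastic reader noise at OD
extremes, and compound interactions. Passing tests therefore demonstrate
correctness of the computation and calibration under idealized noise, not
robustness to systematic plate artifacts — those must still be caught by
the quality flags and by eye.

## Problem sizes in the validation suite

The acceptance tests use the sizes their statements name: 1000 random
draws for normalization and two-point exactness, the full 4×4 transform
grid, a 3×3 grid of noiseless Hill truths, 200 seeded plates for noisy
recovery, and 200 plates × 500 bootstrap replicates for CI coverage. The
acceptance script reports the same quantities with a 100-plate × 300-replicate
coverage run, a size at which the empirical rate is still a meaningful
check of calibration.

## Degenerate inputs and tie-breaks

* A dose whose three wells are all discarded contributes an empty
  triplicate; estimators treat the row as having fewer doses.
* Exactly-flat responses: the linear method refuses (no crossing); the Hill
  fit returns a curve reproducing the level with $R^2$ absent.
* A triplicate mean exactly at 50% never forms a strict bracket for the
  two-point method (and is inside any sensible exclusion band).
* Transform domain violations inside an estimator (e.g. a negative IP under
  a logit axis) refuse rather than raise; domain violations on direct
  transform calls raise, naming the value.
* Manual edits: the first override preserves the original value; restore
  reverts both override and discard; every event stays in the audit log and
  the report prints both original and modified values.

## Configuration defaults

| parameter | default | rationale |
|---|---|---|
| method | nonlinear | standard practice for sigmoidal dose-response |
| x / y transform | log10 / linear | common dose-response convention |
| IC50 type | — (must be stated) | absolute vs relative is a scientific choice; no silent default |
| two-point band | (48, 52) % | near-50% brackets are uninterpretable |
| outlier discard / k | off / 1.0 SD | discarding data is opt-in; k=1 is the smallest round multiplier below the n=3 bound |
| bootstrap B / percentiles | 1000 / (2.5, 97.5) | B where percentile endpoints stabilize; equal-tailed 95% |
| bootstrap failure tolerance | 20% | beyond this the replicate set no longer represents the sampling distribution |
| display digits | 2 | rendering only; stored values are never rounded |
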