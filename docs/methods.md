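# Methods

## The model

Maize is a facultative short-day species: development toward flowering is
paced by temperature throughout the life cycle, while photoperiod acts only
after the plant reaches a sensitized stage, just before tassel initiation.
Under short days tassel initiation is not repressed, so the thermal time
from emergence to tassel initiation under short days — the basic vegetative
phase (BVP) — approximates the duration a genotype needs to become
competent to respond to photoperiod. The photoperiod it then perceives,
the **sensed daylength** DLs, is the daylength on the calendar day its
cumulative thermal time from emergence first reaches its BVP in a given
environment.

The reaction norm relates thermal time from emergence to anthesis
(Tt_em-ant, °Cd) to DLs (h) as a continuous bilinear (hinge) function

    Tt_em-ant = α + β (DLs − e)+ ,

with three physiologically interpretable parameters: flowering time *per
se* α (°Cd, the thermal duration absent photoperiod delay), critical
photoperiod e (h), and photoperiod sensitivity β (°Cd h⁻¹, the delay per
hour of sensed daylength above the threshold).

## Thermal time

Daily mean temperature is converted to a development rate either by the
classic linear degree-day ramp with an optimum cutoff, or by the
Wang–Engel beta response

    f(T) = [2 (T−Tmin)^a (Topt−Tmin)^a − (T−Tmin)^{2a}] / (Topt−Tmin)^{2a},
    a = ln 2 / ln((Tmax−Tmin)/(Topt−Tmin)),

clamped to 0 outside (Tmin, Tmax). Default cardinals are (8, 30, 43) °C —
typical maize values; studies that calibrated their own cardinal set should
configure them. The beta increment is f(T)·t_scale with t_scale defaulting
to Topt−Tmin, which puts beta-based durations on a °Cd-equivalent scale
comparable to linear degree days. One increment is computed per day from
the daily mean; sub-daily integration is not implemented. Accumulation is
day-inclusive: the start date contributes its own increment, and a
threshold is "reached" on the first day the cumulative sum equals or
exceeds it.

## Daylength

Photoperiod uses the closed-form CBM model (revolution angle → solar
declination → day fraction) with a twilight coefficient p in degrees of
solar depression; p = 6 (civil twilight) is the default used for
envirotyping, p = 0 gives geometric sunrise–sunset daylength. All trig is
in radians; day 366 is folded onto 365 (sub-minute effect). At polar
latitudes the model saturates; daylength is clamped to 0/24 h with a
warning rather than raising, although maize networks never approach that
regime. In this parameterization the summer solstice falls at day-of-year
≈ 173. The daily rate of photoperiodic change is the central difference
(D(J+1) − D(J−1))/2 with year wrap-around.

## BVP prediction and maturity references

Because tassel initiation coincides with the formation of the last leaf
primordium and primordium initiation is proportional to leaf-tip
appearance, BVP is predicted as

    BVP = (P_tip / α_phyll/plast) (LF − L_pr,em),

with the phyllochron P_tip (°Cd per leaf), final leaf number LF, the
phyllochron/plastochron ratio α_phyll/plast = 1.73 (literature range
1.58–1.85), and L_pr,em = 5.5 primordia already present at emergence.
Reference maturity classes early/median/late are fixed at 239/326/434 °Cd
(the 5th/50th/95th percentiles of a large-panel BVP distribution).
Percentiles of user BVP samples use linear-interpolation empirical
quantiles (the numpy default), chosen for reproducibility since several
quantile conventions are in common use.

## Envirotyping

Emergence is the observed date when recorded, otherwise the crossing of
76 °Cd accumulated from sowing. The sensitization date is the crossing of
the BVP accumulated from emergence; DLs and the photoperiodic change rate
are evaluated at that date's day of year using latitude only (no
longitude/timezone correction — the daylength model needs none). Both
common-reference and genotype-specific envirotyping are supported: the API
accepts a maturity label, a bare BVP in °Cd, or a genotype's development
parameters. Network-level summaries include the DLs range and same-site
inter-annual differences (sites keyed on lat/lon rounded to 2 decimals).
Weather must cover sowing through a configurable horizon (default
250 days); environments whose record ends before a crossing are reported
as named failures, not fatal errors.

## Latent-variable adjustment

Photoperiod-insensitive control genotypes should flower at the same
thermal time in every environment; their environment-specific deviations
from their across-environment mean estimate latent environmental effects
(management, weather bias, drought, ...). Each environment is mapped to
exactly one control set; the deviation is subtracted from every
non-control observation in that environment and control observations are
set to the across-environment mean. Deviations within a set sum to zero,
which means only the *centered* part of any latent effect is identifiable
— a grand-mean offset is absorbed into the controls' flowering time per se.
Control observations are retained (at the set mean) rather than dropped.

## Hinge estimation

For a fixed threshold e the model is linear in (α, β), so the fit profiles
the residual sum of squares over e: a coarse scan over all unique observed
DLs values and midpoints, followed by bounded scalar minimization inside
the intervals bracketing the best coarse candidates. The refinement step
exists because the profile RSS is smooth between consecutive data values
and its minimum can fall strictly inside an interval; with it the
estimator reproduces an exhaustive 0.01 h grid search (verified against
that brute-force oracle in the tests). Candidate thresholds must leave at
least 3 observations strictly on each side. A "linear limit" candidate at
the minimum observed DLs — where the hinge degenerates to a straight line
— is always evaluated so the hinge never fits worse than the best line; if
it wins, the fit is flagged `linear_limit`. Negative slopes are permitted
but flagged (`negative_slope`) rather than constrained. The profile RSS
can be nearly flat, in which case the threshold is reported at the global
numerical minimum; ties at machine precision resolve to the first
candidate scanned.

Standard errors for α and β are conditional OLS errors given the estimated
threshold, with variance RSS/(n−3) to account for the three estimated
parameters; the threshold SE is a nonparametric bootstrap (default 1000
resamples, seeded; resamples whose DLs or response collapse to a constant
are skipped). RMSE is reported as sqrt(RSS/n) for the full bilinear model.

## LD–SD estimation

When DLs coverage cannot support threshold detection (sparse data, a
coverage gap across the plausible critical-photoperiod range, or
insensitive genotypes), the linear LD–SD method is used: observations are
classified short-day/long-day at 13.5 h (the boundary value itself goes to
SD — an arbitrary but fixed convention), each observation's predictor is
recoded to its group's mean DLs computed over the genotype's own observed
environments, and the predictors are shifted so the SD mean is zero. OLS
then yields α at the SD mean and β as the slope between group means; with
two predictor levels this equals the difference-of-means formula
regardless of group sizes.

The LD–SD slope is a biased estimate of β when the true critical
photoperiod e differs from the SD-DLs mean. The direction stated for real
material — upward when e is below the SD mean, downward when above —
follows from short-day physiology in which SD environments express no
photoperiod delay at all (the floral-repression pathway is not induced
under short days), so the whole rise β(x̄_LD − e) is spread over the
span x̄_LD − x̄_SD. Note that under a *pure* hinge data-generating model,
where any environment with DLs > e responds, the estimator is never upward
biased (E[(x−e)+] ≥ x̄−e pointwise); the bias simulations in this package
therefore use the SD-gated generative model, which is the biologically
meaningful case.

## Synthetic data

The generator emulates the study conditions the analysis assumes.
Temperature: tmean(d) = 18 + 8·sin(2π(DOY−105)/365)·(|lat|/45) +
N(0, 1.5) °C, tmin/tmax at ∓5 °C — an annual sinusoid peaking in
mid-July whose amplitude grows with latitude. Networks: latitudes uniform
on 14–50 °N with sowing dates staggered by latitude (DOY = 270 −
4.6·(lat−14) ± 20): spring sowing at temperate sites grading into autumn
sowing in the tropics, which yields continuous DLs coverage of roughly
12.2–17 h across both sides of typical maize critical photoperiods — the
same property real hemisphere-wide MET networks rely on. Panels: (α, e, β)
drawn per ancestry/sensitivity group, with an insensitive fraction at
β = 0 usable as controls; phyllochron ~N(34.6, 3) °Cd and final leaf
number ~N(16.5, 1.5) give each genotype a BVP through the development
formalism. Phenotypes are forward-simulated as Tt* = α + β(DLs−e)+ +
λ_env + ε with λ_env ~ N(0, 40) °Cd shared within an environment and
ε ~ N(0, 20) °Cd, then snapped to the first calendar day the cumulative
thermal time reaches Tt*; days to anthesis are integer days from sowing.
The snap makes the realized thermal time exceed the target by at most one
day's increment (≈ 14 °Cd at the optimum under the beta defaults), which
is the dominant tolerance in round-trip recovery tests.

Two presets ship: `d4-like` (14 genotypes, half insensitive, 37
environments, continuous coverage) and `d5-like` (236 genotypes in three
ancestry groups, 19 environments in two DLs clusters with a gap between
roughly 12.4 and 14.5 h, where only the LD–SD method is usable).

What the generator does **not** emulate: spatially correlated weather,
weather autocorrelation beyond the seasonal sinusoid, latitude-dependent
mean temperature, unbalanced genotype presence across environments,
drought or management gradients with structure (latent effects are iid
Gaussian), or measurement error in the development parameters. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated noise model, not robustness to every
property of real MET data.

## Problem sizes and numerical choices

Recovery experiments use 100 replicate METs of 40 environments each with a
single sensitive genotype (α = 850 °Cd, e = 13.0 h, β = 60 °Cd h⁻¹,
residual sd 20 °Cd), and the adjustment experiments add five control
genotypes and latent offsets of sd 40 °Cd — sizes representative of a
well-powered single-genotype reaction-norm study. Threshold refinement
uses `scipy.optimize.minimize_scalar` (bounded, xatol 1e-8) with interval
endpoints nudged by 1e-9 to keep the side-count rule well-defined.
Degenerate inputs raise typed errors: constant response (threshold
unidentifiable), zero DLs spread, fewer than 8 points, no admissible
interior candidate (with a pointer to the LD–SD method), single-class
LD–SD data.

## Limitations

- Daily-mean thermal time only; hourly integration is future work.
- The exact cardinal temperatures used by any particular published
  calibration must be supplied by the user; defaults are literature-typical.
- No mixed-model BLUE estimation, Finlay–Wilkinson regression, mixture
  modelling of bilinear and linear genotypes, or genomic prediction.
- Bootstrap threshold SEs are approximate; the profile-RSS surface can be
  flat when coverage near the threshold is thin, and the reported SE will
  then be large.
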