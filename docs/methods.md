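# Methods

This note documents the models implemented by `ivivckit`, the assumptions
behind them, the numerical choices, and the limits of what the synthetic
test-bed can demonstrate.

## Data model and units

The canonical internal time unit is **minutes**. Hours appear in exactly two
places: at I/O, and in reported dissolution-model parameters (MDT, Tmax and
lag are conventionally quoted in hours, while PK sampling times are quoted
in minutes). `TimeProfile` carries a declared value kind — unitless
fraction, concentration (ng/mL) or amount (µg) — and enforces strictly
increasing, finite, non-negative times. Fraction profiles may overshoot 1
slightly from assay noise; values above 1.05 are flagged with a warning
rather than rejected.

Monotone interpolation (PCHIP) is the default for cumulative quantities
(dissolution, absorption) because linear or spline interpolants can
overshoot and break monotonicity; plain linear interpolation is used for
concentrations. Resampling refuses to extrapolate.

## Biopharmaceutics classification

The dose number is `D0 = (M0/V0)/Cs` with `V0 = 250 mL` (exposed as a
parameter) and `M0` the content of the component in one administered dose —
for a multi-component tablet there is no labelled per-compound dose, so the
content per tablet times tablets per dose stands in for the maximum dose.
`D0` is reported per medium (each medium's own solubility), while the
solubility *class* uses the minimum solubility across pH 1.2, 4.5 and 6.8
(equivalently the maximum D0): high when that D0 ≤ 1. Censored solubilities
(assay saturated, value is a lower bound) are carried with a flag; the bound
is used for D0, which is then an upper bound.

Permeability is `Peff = (dQ/dt)/(A·C0)` with the transport rate per second,
the 24-well transwell membrane area `A = 0.33 cm²` as default, and the
high/low threshold at 1 × 10⁻⁶ cm/s. A slope helper estimates dQ/dt by
least squares from replacement-corrected receiver amounts sampled in
minutes. The BCS class is the standard 2×2 table of the two classes.

## Cumulative dissolution and release models

Sampling with medium replacement dilutes later samples; the corrected
cumulative fraction is

    Dn = (Cn·V1 + V2·Σ_{i=1..n-1} Ci) / M.

The multiplication by 100 % happens only in reports; internally fractions
stay in [0, 1].

Three empirical release models are fitted (t in hours):

* Hill: `F = Finf·t^b/(MDT^b + t^b)` — half its plateau at `t = MDT`.
* Weibull: `F = Finf·(1 − exp[−((t − tlag)/MDT)^b])`, 0 before the lag.
  The lag is fixed at 0 by default and estimable on request.
* Makoid–Banakar: `F = Fmax·(t/Tmax)^b·exp[b(1 − t/Tmax)]` for `t ≤ Tmax`
  and `F = Fmax` beyond — the piecewise plateau form.

The plateau is **estimated** by default (bounded at 1.2), not fixed at 1:
tablet dissolution of complex botanical matrices routinely plateaus at
60–90 %, and a forced plateau of 1 biases MDT and b. `finf_fixed=True`
restores the constrained variant.

Fitting is multi-start least squares (lmfit/Levenberg–Marquardt): MDT
starts at the empirical 25/50/75 % quantile times, shape `b` at
{0.5, 1, 2, 4}, plateau at the observed maximum. The reported correlation
coefficient is the Pearson correlation of fitted vs observed values
(`r_method="rsq"` gives √(1 − SSR/SST) instead). AIC uses the
least-squares form `n·ln(SSR/n) + 2k`; because software packages differ in
additive constants, absolute AIC values are comparable only within one
fitting session — selection uses the highest R with ties (|ΔR| < 10⁻⁴)
broken by the smaller AIC. Fitting operates on the vessel-mean profile;
per-vessel fits are available but not the default.

## NCA and the unit impulse response

NCA is deliberately model-free: Cmax/Tmax are read off the observed points,
AUC(0–t) is the linear trapezoid, λz comes from a log-linear regression over
the terminal window (≥ 3 declining points after and excluding Cmax) chosen
by the best adjusted R², `t½ = ln2/λz` and
`AUC(0–∞) = AUC(0–t) + Clast/λz`. When no declining terminal phase exists
the extrapolated quantities are reported as NaN, never guessed.

Absolute bioavailability is `F% = 100·(AUC_po/D_po)/(AUC_iv/D_iv)` using
**AUC(0–t)** — the variant validated against the reference study's printed
values; AUC(0–∞) can be substituted by the caller.

The disposition kernel is a polyexponential with optional lag,
`UIR(t) = Σ Aᵢ·e^{−αᵢ(t−tlag)}` for `t ≥ tlag`, dose-normalised, fitted by
weighted least squares to the IV reference profile. Candidate weightings —
uniform, 1/Y, 1/Y², and the predicted-value schemes 1/Ŷ, 1/Ŷ² applied with
two reweighting passes — are scanned and the winner chosen by AIC (weights
normalised to mean 1 so the criteria are comparable). Amplitude starts come
from a linear solve on the exponential basis at stripped-slope starting
rates. If the two rate constants collapse within 10⁻⁶ min⁻¹ the model is
refitted with one term and flagged. The printed formulation of this kernel
in some sources mixes an absorption rate constant into the IV disposition
and has a sign ambiguity; the standard decaying polyexponential is the form
consistent with reported parameter tables and with deconvolution theory,
and is what is implemented.

## Numerical deconvolution

The observed oral concentration is `C(t) = ∫ r(τ)·UIR(t − τ) dτ` for an
unknown input rate `r ≥ 0`. Discretisation: `r` is a staircase on a uniform
grid (default step 5 min); each element of the lower-triangular system
matrix is the **exact** integral of the polyexponential kernel over a grid
interval (no quadrature error), so the staircase is the only approximation.
Because observed PK profiles are sparse relative to the rate grid, the oral
profile is first interpolated (PCHIP) onto the grid, making the system
square; it is then solved by non-negative least squares — absorbed amount
cannot decrease, and the constraint regularises the classic oscillation of
unconstrained deconvolution. A condition number above 10¹⁰ aborts with
advice to coarsen the grid.

The cumulative input is normalised by its own plateau: `Fabs` is the
fraction of the *ultimately absorbed* amount, so correlation models relate
fractions to fractions and absolute bioavailability enters only at
prediction time. Wagner–Nelson (`Fabs ∝ C + ke·AUC(0..t)`, plateau-
normalised) serves as an independent oracle on one-compartment data; the
two methods agree to well under 1 % sup-norm there.

## Correlation forms, prediction, validation

Four nested forms map in vivo time through the in vitro curve:

    F1: Fabs = AbsScale·Diss(Tvivo)
    F2: Fabs = AbsScale·Diss(Tscale·Tvivo)
    F3: Fabs = AbsScale·Diss(Tscale·Tvivo − Tshift)
    F4: Fabs = AbsScale·(Diss(Tscale·Tvivo − Tshift) − AbsBase)

`Diss` evaluates to 0 for negative (pre-lag) arguments. Tvivo and Tshift
are in minutes. Fits are multi-start least squares with Tscale bounded in
[10⁻³, 10³]; a solution pinned at those bounds is flagged
non-identifiable. Selection uses the highest adjusted R (rounded to 4
decimals), ties broken by smaller AIC then SBC. Because `Fabs` is
normalised to its own plateau while `Diss` plateaus below 1, `AbsScale`
absorbs the plateau ratio; the separately estimated fraction-absorbed
`f_abs_total` (from training-data bioavailability) converts back to
amounts at prediction time. Published parameterisations that fold absolute
bioavailability into AbsScale will therefore differ in parameter values but
not in predictions.

Prediction clamps the correlation output to [0, 1], forces it
non-decreasing, and uses its exact increments over each grid interval as
the staircase input rate — the exact integral of the model's derivative, so
mass balance holds to machine precision and the predicted AUC approaches
`dose·f_abs_total·Σ Aᵢ/αᵢ` when input completes. Validation computes NCA
on the predicted curve and the signed error
`PE% = 100·(VP − V0)/V0`; the model passes when |PE| ≤ 15 for *both* Cmax
and AUC (the bound is inclusive).

## Multi-component integration

Within a BCS class, dissolution profiles combine as a convex combination
with content weights `Wᵢ = Nᵢ/ΣN` (weights sum to 1 within 10⁻¹²), and
plasma profiles combine as a plain unweighted sum of concentrations at
shared time points — an optional weights argument exposes per-component
scaling but defaults to 1, following the integration formula rather than
its prose gloss. Mass concentrations of different molecules are summed as
printed; a molar variant would need molecular weights the data model does
not carry. The integrated profiles run through exactly the same estimator
stack as single components; a one-member group reduces to the
single-component result identically.

## Synthetic data generator

The generator emulates the *structure* of the emulated study: paddle
dissolution at 75 rpm in 900 mL with 3 mL replaced samples on the
15–360 min grid (truncated at 180 min in 0.1 M HCl for gastric emptying),
six vessels; crossover PK in six subjects on the 15–1440 min grid, IV
reference bolus vs oral tablets. Ground-truth release curves use
Hill/Weibull parameters in the fitted range (plateaus 0.6–0.9, MDT 1–3 h);
disposition is biexponential with half-lives of ~1.5 h and ~2 days;
oral input is first-order with lag, or dissolution-limited (rate follows
the in vitro curve) for end-to-end correlation experiments. Concentrations
are back-computed from the release curve so the replacement correction
inverts exactly in the noise-free limit. Noise is proportional log-normal —
assay CVs of 1–11 % are typical for LC-MS/MS bioanalysis, motivating the
10 % default — plus an optional additive floor. All randomness derives from
one scenario seed (component/medium names are mixed in via CRC32, so runs
are reproducible across processes).

What passing tests on this generator do **not** show: real dissolution
noise is not log-normal i.i.d. (vessel effects, filtering losses),
real absorption is neither purely first-order nor exactly
dissolution-limited (GI transit, regional permeability), and real
inter-subject variability is structured rather than multiplicative. The
test-bed validates the *numerics* — parameter recovery, deconvolution
fidelity, selection logic, mass balance — not biological realism.

## Problem sizes and determinism

Default experiment sizes keep the whole suite light: parameter-recovery
studies use 50 seeds at 2 % CV, and the end-to-end pipeline check uses 20
seeds at 10 % CV, both at the standard sampling grids; deconvolution
oracles run on 1-min grids over 12 h windows. The study runner reruns
byte-identically for a fixed seed. All fits are deterministic multi-start
local optimisations — no stochastic optimisers.

## Known limitations

* Level B/C correlations (single-point metrics) are out of scope.
* Loo–Riegelman (two-compartment absorption) is not implemented; the
  Wagner–Nelson oracle covers the one-compartment case only.
* Per-subject (population) IVIVC is not modelled; fitting operates on mean
  profiles, matching the mean-curve convention of the study design
  emulated here.
* UIR fitting supports one or two exponential terms.
* The f₂ similarity factor and mechanistic disintegration models are not
  provided.
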