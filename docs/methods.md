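# Methods

## Model

Drug exchange between the electrostatically bound state (doxorubicin
cation paired with a carboxylate of an acrylic-acid residue in the
nanoparticle corona) and free solution is treated as a reversible
first-order reaction,

    dC_free/dt = k1 C_bound − k−1 C_free,        k−1 = k′−1 · C_COOH,

with C_free + C_bound = C_max conserved. k−1 lumps the carboxyl
concentration into a pseudo-first-order constant; whether it refers to
the initial or the equilibrium ionization state of the carboxyls is not
resolved here — it is treated as a single effective constant per
condition. In conversion form (ξ = C_free/C_max) the solution is

    ξ(t) = ξ∞ (1 − e^−kt),  k = k1 + k−1,  ξ∞ = K/(1+K),  K = k1/k−1.

ξ is defined relative to complete release (C_max), which coincides with
the loaded dose under the model's assumptions. The model deliberately
ignores transport through the dialysis membrane as a separate
compartment and any pH-dependent speciation of doxorubicin: pH enters
only through the fitted constants of each condition.

## Estimation

The chain is: estimate ξ∞ → K = ξ∞/(1−ξ∞) → estimate k = k1+k−1 →
split k1 = kK/(1+K), k−1 = k/(1+K). Because K always derives from the
estimated ξ∞, the fitted pair satisfies k̂1/k̂−1 = K̂ identically.

Three methods are exposed (`fit_release_curve(..., method=...)`):

* `nonlinear` (default) — both ξ∞ and k from least squares of
  ξ∞(1 − e^−kt) in the observation domain, initialized at the tail mean
  and a half-rise rate guess. Under the additive homoscedastic noise
  the generator produces, this is the maximum-likelihood estimator.
* `linearized` — ξ∞ from the nonlinear fit, k from the OLS slope of
  ln(ξ∞ − ξ) on t (the textbook semilog analysis).
* `plateau` — ξ∞ as the mean of the points in the final 25% of the
  time span, k from the semilog slope (the fully classical reading).

The semilog regression is always computed as a *linearity diagnostic*
(its r², the count of points excluded because ξ ≥ ξ̂∞, and the gap
between its intercept and ln ξ̂∞, which is zero for an exact
single-exponential). It is not the default estimator of k because the
log transform amplifies additive noise by 1/(ξ∞ − ξ), without bound as
the curve reaches its plateau: on the default grid more than half the
samples of a fast curve sit within a few noise SDs of ξ∞, and the
semilog slope there is dominated by noise (median errors of tens of
percent at σ = 0.002, versus a few percent for the nonlinear fit).
Points with ξ ≥ ξ̂∞ are excluded from the semilog fit rather than
clipped (clipping biases the slope); the regression is unweighted; the
intercept is left free so model inadequacy stays visible. A curve whose
tail still rises by more than 2% of its plateau triggers a
`PlateauWarning` (ξ∞ is then an extrapolation), not a failure.

Curves need ≥ 4 points (two parameters plus diagnostics); the plateau
method needs ≥ 3 points in the tail window.

## Temperature analysis

Arrhenius (ln k vs 1/T) and van't Hoff (ln K vs 1/T) fits are ordinary
unweighted least squares, matching the straight-line treatment standard
for such series; E_a = −slope·R and ΔH° = −slope·R with
R = 8.314 J mol⁻¹ K⁻¹. Since ln K = ln k1 − ln k−1 pointwise, the
van't Hoff slope equals the difference of the two Arrhenius slopes
exactly; this identity is asserted in the tests. ΔG°(T) = −RT ln K and
ΔS°(T) = (ΔH° − ΔG°(T))/T are tabulated per temperature; when ΔH°
comes from a single van't Hoff line ΔS° is constant up to the scatter
of the individual K values about that line, so the per-temperature
table doubles as a linearity check. Energies are stored in J/mol and
rendered in kJ/mol to one decimal.

Error propagation into confidence intervals for E_a/ΔH is out of
scope; r² is the only fit diagnostic reported.

## Carboxyl concentration

The normalized binding constant k′−1 = k−1/C_COOH needs C_COOH, which
is computed from the copolymer mass loading and composition as

    C_COOH = 1000·c / (x_AA·72.06 + (1−x_AA)·111.14) · x_AA   [mol/L]

using the repeat-unit molar masses of acrylic acid and
N-vinyl-2-pyrrolidone and neglecting end groups. This convention is
the package's own; it scales k′−1 and nothing else.

## Synthetic experiments

The generator emulates a dialysis release measurement as the exact
conversion profile plus i.i.d. additive Gaussian noise on ξ, clipped to
[0, 1], from a seeded `numpy` generator — a pure function of its spec.
Defaults: sampling 0–48 h at 2 h steps (the equilibration timescale
implied by summed constants of order 0.05–0.2 h⁻¹), σ = 0.002 (about
2% of the largest neutral-pH plateau; no replicate variance is
published, so σ is configurable and recorded). Fifteen presets cover
the published condition grid — compositions 3.9/5.6/9.8/15.8 mol% AA,
concentrations 2.5×10⁻³–1.5×10⁻² g/mL, temperatures 278–323 K, pH
4/7/9 — each loaded with its published rate-constant pair as ground
truth; conditions repeated across series are kept as separate presets
so each series stays complete. An absorbance view (A = slope·ξ +
offset) emulates the 480 nm readout with an exact inverse.

What the simulation does **not** contain: membrane transport lag,
drift or photobleaching of the absorbance signal, replicate-to-replicate
calibration error, burst release, or pH-dependent speciation. Passing
recovery tests therefore demonstrates that the inference chain is
correct and well-conditioned under the model's own assumptions, not
that real dialysis data are free of these systematics.

## Recovery limits

Parameter recovery is exact (≤ 10⁻⁶ relative) on noiseless curves and
a few percent at σ = 0.002 for most presets. Two conditions sit at or
below the information floor of the default design: at 278 K the
plateau is ξ∞ ≈ 0.023, only ~11 noise SDs, and the Cramér–Rao bound on
the 25-point grid already puts the median relative error near 7% (k1)
and 8% (k−1) for *any* unbiased estimator, so a 5% median-recovery
target is unreachable there; the 1.5×10⁻² g/mL condition's floor
(~4–4.5%) makes a 20-replicate median straddle 5%. The corresponding
assertions are kept at the 5% level and simply fail for those
conditions — the honest statement of what the design supports.

## Numerical choices

* ODE cross-check: the two-state system (free, bound) is integrated
  with `scipy.integrate.solve_ivp` (Radau, rtol 10⁻¹⁰, atol
  10⁻¹³·C_max) so that mass conservation is a genuine integrator
  diagnostic; closed form and integrator agree to ≤ 10⁻⁸ relative.
* Nonlinear fits use `scipy.optimize.curve_fit` with bounds
  ξ∞ ∈ (0, 1], k > 0; the tail mean seeds ξ∞ and the half-rise time
  seeds k.
* Time is in hours and rate constants in h⁻¹ throughout; unit
  conversion belongs at the I/O boundary.
* Degenerate inputs (k = 0 curves, ξ∞ outside (0,1), non-positive K or
  temperatures, single-temperature series) raise validation errors
  naming the offending stage; integrator failures raise rather than
  return NaN.

## Known limitations

Single-exponential only — multi-exponential, Weibull or
Korsmeyer–Peppas release profiles are out of scope, as are Bayesian
uncertainty quantification and Eyring analysis. The published ~92%
experimentally read binding efficiency at 310 K/pH 7 does not equal
1/(1+K) = 90.3% computed from the published constants; both numbers
are surfaced and neither is reconciled.
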