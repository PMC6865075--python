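# Methods

## Scope and model

The package estimates, per amino-acid model system:

1. **Per-temperature formation kinetics.** Concentration–time series below
   the degradation onset are fit to the lagged first-order model
   C(t) = A(1 − e^(−k(t−t₀))), clamped to C = 0 for t < t₀ (the lag is a
   period before any formation; the raw formula would be negative there).
   A is the asymptotic maximum concentration (µg/mL), k the formation rate
   constant (min⁻¹), t₀ the lag (min).
2. **Per-temperature degradation kinetics.** Series whose replicate-mean
   peak occurs before the final time, with the final mean more than a
   configurable fraction (default 0.05) below the peak, are in the
   degradation regime. k_d is minus the slope of ln(mean C) against time
   *elapsed since the peak* — CA₀ in k = −ln(CA/CA₀)/t is the
   pre-degradation maximum, so elapsed time starts there, and with only two
   usable points the regression reduces exactly to that two-point formula.
3. **Arrhenius regression.** Ordinary least squares of ln k on 1/T over the
   formation-regime temperatures; Ea = −slope·R (kJ/mol). Two pairs are the
   minimum and then the fit is the exact two-point closed form.
4. **Eyring transition state.** ΔH‡ = Ea − R·T̄ with T̄ the arithmetic mean
   of the formation temperatures in kelvin — a single representative
   enthalpy for the regression window. ΔS‡ is the mean of the pointwise
   Eyring entropies R[ln(k·h/(k_B·T)) + ΔH‡/(R·T)] over the same (k, T)
   pairs. ΔS‡ < 0 is classified bimolecular, ΔS‡ > 0 monomolecular,
   exactly 0 indeterminate (only the strict inequalities carry meaning).

## Conventions that matter

* **Entropy convention.** The default (`paper`) evaluates the Eyring
  entropy with k in min⁻¹ against the frequency factor k_B·T/h in s⁻¹.
  This is dimensionally inconsistent but is the convention under which the
  reference activation entropies for these systems were reported; the
  dimensionally consistent `si` convention (k converted to s⁻¹) is
  available and differs by exactly −R·ln 60 ≈ −34.04 J/(mol·K) at every
  input. Fidelity first, correctness available.
* **Constants.** R = 8.3145 J/(mol·K), k_B = 1.381 × 10⁻²³ J/K,
  h = 6.626 × 10⁻³⁴ J·s; celsius → kelvin uses +273.15 (configurable; the
  273 vs 273.15 difference is < 0.04 % in every output).
* **Non-detects.** A non-detect before the first detection is a true zero
  and enters the formation fit (it pins the lag). A non-detect after a
  detection cannot be distinguished from below-quantification signal and
  is treated as missing.
* **R².** 1 − SS_res/SS_tot about the mean, for nonlinear fits too; it can
  be negative for terrible fits and is reported as-is.

## Fitting procedure

Formation fits pool all replicate points (replicate means are reported
separately by the pipeline). The solver is bounded trust-region least
squares (A, k > 0; 0 ≤ t₀ ≤ t_max) with a deterministic multi-start grid:
A₀ ∈ {1.05·max C, 2·max C}; k₀ from the log-slope of the first two
detected points (clipped to [10⁻³, 10]); t₀ ∈ {0, latest leading
non-detect time}. The start with the smallest final SSE wins, ties broken
toward the smaller t₀; tolerances 10⁻¹⁰ on relative SSE change, at most
10⁴ evaluations. A failed solve returns `converged=False` rather than
parameters. There is no weighting or robustification, and no uncertainty
intervals on the kinetic parameters.

## Synthetic-data generator

The generator mirrors the experimental design: 150–270 °C in 30 °C steps,
4–16 min in 4 min steps, duplicate measurements. Three built-in system
profiles emulate the study's amino acids:

* **phenylalanine-like** — fast former, Ea 95.36 kJ/mol; the
  pre-exponential is anchored so the 210 °C rate is 0.0710 min⁻¹ (this
  also reproduces the 150 °C reference rate, 0.00245 vs 0.0024 min⁻¹; the
  three reference rates are not mutually Arrhenius-consistent, so one
  anchor had to be chosen and the best-measured steep-rise temperature was
  used); plateaus 10–24 µg/mL; degradation above 210 °C with a peak of
  ≈ 21.5 µg/mL at 8 min at 240 °C.
* **proline-like** — slow former, Ea 114.12 kJ/mol anchored to its 180 °C
  rate (0.0268 min⁻¹); sub-µg/mL plateaus; nothing detectable at 150 °C
  and a lag past the first time point at 180 °C; degradation above 210 °C
  with the peak at 4 min (the observed proline peak time).
* **glycine-like** — forms no product; every observation is a non-detect.

Above the onset the true curve rises along the formation model to a peak
(at the second design time by default, or the profile's `peak_time`) and
then decays exponentially at the profile's k_d(T), interpolated on a log
scale between the reference 240/270 °C decay rates. Observations are
truth × (1 + ε_p) + ε_a with Gaussian ε (defaults 5 % proportional,
0.005 µg/mL absolute), truncated at zero; values below the limit of
quantification (0.002 µg/mL) become non-detects. A zero truth yields a
clean non-detect — noise models measurement error on an existing
chromatographic peak, not the creation of peaks from nothing. Streams are
seeded per (seed, system, temperature), so identical inputs give
bit-identical datasets. The LOQ is kept on the µg/mL scale of the reported
concentrations.

What the generator does **not** emulate: calibration/instrument drift,
non-Gaussian replicate error (only the order of magnitude of the reported
standard deviations is matched), any mechanistic crossover between
formation and degradation (the peak-then-decay shape is imposed), and the
2× inconsistency discussed below. Passing recovery tests therefore show
the estimation chain is correct under the stated error model, not that
real chromatographic data will behave this well.

## Identifiability limits (please read before trusting noisy fits)

At 150 °C the phenylalanine-like rate is ≈ 0.0025 min⁻¹, so over a 16-min
window only the initial linear rise is observed: A and k are then jointly
unidentifiable (only their product is constrained), and with any noise at
all the fitted k can be off by an order of magnitude even though R² looks
excellent. This propagates into a three-temperature Arrhenius regression —
simulation at 1 % proportional noise shows median Ea errors of tens of
percent. This is a property of the design (short window, slow rate), not
of the solver: a profiled global grid search confirms the optimizer
reaches the global least-squares optimum. Noise-free data are recovered
exactly. Even at the well-conditioned 210 °C design, a Cramér–Rao analysis
with 5 % proportional noise puts the per-fit spread of k̂ near 44 %, and
the unweighted least-squares estimator carries a ≈ +10 % median bias in k
at that noise level. Treat single-temperature rate constants from 4-point
series as order-of-magnitude estimates unless the rise curvature is well
sampled.

## Known inconsistencies in the reference values

* The reference proline activation energy (114.12 kJ/mol) is not derivable
  from its two reported formation rate constants — the two-point formula
  gives ≈ 229 kJ/mol, almost exactly 2×. The pipeline's regression is the
  plain OLS definition and does not attempt to imitate whatever produced
  114.12; the synthetic proline profile simply *generates* from
  Ea = 114.12, so its 210 °C rate (≈ 0.18 min⁻¹) differs from the reported
  1.1757 min⁻¹.
* The reported per-temperature degradation rates cannot be reproduced from
  any reported concentration pair; the generator uses them as ground truth
  for decay, nothing more.
* The reference entropy aggregation is inconsistent between systems (one
  matches a three-temperature mean, the other a single-temperature point);
  this package always uses the mean over the formation pairs.

## Pipeline and numerics

Input is a tidy CSV (`amino_acid,temperature_C,time_min,replicate,
concentration_ug_per_mL`, `nd` for non-detects). Outputs are
`kinetics_table.csv`, `thermodynamics_table.csv`, and `report.json`; rates
are printed at 4 significant figures, concentrations, lags and energies at
2 decimals (the report JSON keeps full precision), and every file embeds a
hash of the run configuration, so a run is reproducible byte-for-byte from
its stored config and input. Logging goes to standard error only.

## Problem sizes used in the validation suite

The test suite exercises recovery at the native design size (8 points per
series, 15 series per dataset); Monte-Carlo checks use 100–200 seeded
replicates of a single-temperature series, which the suite completes in
seconds.
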