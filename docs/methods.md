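# Methods

`loxsense` characterizes FMN-dependent L-lactate oxidases (LOx) twice
over: in solution, through steady-state kinetics, and immobilized on a
mediated rotating-disc electrode (RDE), through Koutecký–Levich (KL)
analysis of amperometry. This note records the models, the defaults and
their rationale, what the synthetic data do and do not emulate, and the
numerical choices.

## Solution kinetics

**Michaelis–Menten.** Initial rates v = Vmax·[S]/(Km+[S]) are fitted by
unweighted nonlinear least squares over individual replicate points.
LOx is a two-substrate (ping-pong) enzyme; with oxygen fixed at ambient
~250 µM the fitted constants are *apparent* constants, which is the
operating condition of an air-exposed biosensor. Rates in turnover
units (s⁻¹, volumetric rate over monomer enzyme concentration) make
Vmax ≡ kcat; volumetric data (µM/min) carry a units tag and convert
through the assay's monomer concentration. Standard errors come from
the Jacobian covariance at the optimum; the specificity constant is
kcat/Km (mM⁻¹ s⁻¹).

**Product inhibition.** Pyruvate inhibition is fitted globally over the
(substrate × pyruvate) grid with the four classical reversible laws:

* competitive: v = Vmax·S/(Km(1+I/Ki)+S)
* uncompetitive: v = Vmax·S/(Km+S(1+I/Ki))
* noncompetitive: v = Vmax·S/((Km+S)(1+I/Ki))
* mixed: v = Vmax·S/(Km(1+I/Ki)+S(1+I/(α·Ki)))

The mixed law uses the interaction-factor (α) parameterization rather
than two separate Ki values; α = 1 degenerates to noncompetitive.

**Model selection.** The three 3-parameter laws are each nested in the
4-parameter mixed law, so the extra-sum-of-squares F-test applies:
F = ((RSS_s−RSS_c)/(dof_s−dof_c))/(RSS_c/dof_c), p from
F(dof_s−dof_c, dof_c). The four laws are not mutually nested, so the
procedure is: fit all four; among the 3-parameter laws the lowest RSS
wins; mixed is chosen only when it beats that law at the 0.05 level.
Two numerical guards: a negative extra sum of squares clamps F to 0,
and when the simpler law's RSS is already below 1e-10 of the total sum
of squares (both laws interpolating noiseless data to round-off) the
improvement is declared non-significant — otherwise the F-test would be
evaluated on a ratio of machine-epsilon-sized residuals and select the
extra parameter spuriously.

**Optimizer.** `scipy.optimize.curve_fit` from data-driven starts
(Km₀ = median [S], Vmax₀ = max rate, Ki₀ = median nonzero [I], α₀ = 1),
with up to three deterministically log-jittered restarts on failure.
Fits with non-positive parameters, undefined standard errors, or (for
Michaelis–Menten) Km collapsing to the zero boundary — the signature of
an all-saturating design — are flagged non-converged rather than raised.

**Thermal inactivation.** Residual activity after a fixed incubation is
fitted with a two-parameter logistic, activity = 100/(1+exp((T−T50)/w)),
asymptotes fixed at 100% and 0%. T50 is reported to 0.1 °C, the
customary precision. A four-parameter variant was considered and
rejected as default: residual activities are normalized to the
unheated control, pinning the asymptotes.

**pH window.** Profiles are normalized to their maximum (=100%) and the
contiguous measured-pH interval ≥ 80% containing the maximum is
reported at the measured grid resolution (0.5 pH units by default), no
interpolation — matching how pH optima are conventionally quoted.
Disjoint super-threshold intervals are flagged.

## Electrochemistry

**Current model.** The sensor current on the mediated
(PEDOT:PSS–Prussian Blue) RDE is a series-resistance (reciprocal-sum)
model:

1/i = 1/i_mt + 1/i_film + 1/i_enz

* i_mt = 0.62·n·F·A·D^{2/3}·ν^{-1/6}·C·ω^{1/2} (Levich, bulk transport)
* i_film = n·F·A·P·C (film transport, permeability P lumped)
* i_enz = n·F·A·k2·Km·C/(Km+C) (enzyme reaction)

Only i_mt depends on ω, so 1/i is exactly linear in ω^{-1/2}; noiseless
KL regressions have r² = 1 by construction. k2 is a heterogeneous rate
constant (area-normalized current against a volumetric concentration →
units of length/time, reported in m/s; internally cm/s with CGS units
throughout and converters at the boundary).

**Analysis chain.** Amperograms are Savitzky–Golay smoothed (window 11
samples, polynomial order 2 — mild smoothing that leaves a plateau
mean unbiased), reduced to per-speed steady-state magnitudes as the
mean over the last half of each speed segment (`tail_frac = 0.5`,
chosen so a 1 s settling transient decays to < 0.1% bias within the
shortest segments used), and regressed as 1/i on ω^{-1/2} by ordinary
least squares. Then:

* D = [1/(0.62·n·F·A·ν^{-1/6}·C·slope)]^{3/2}, averaged over the
  measured concentrations;
* k2 = i_KL·(Km+C)/(n·F·A·Km·C) with i_KL = 1/intercept and Km from the
  solution fit of the same enzyme, averaged over concentrations and
  computed at the lowest enzyme loading, where the intercept is
  enzyme-limited (the inversion assumes the film term contributes
  little to the intercept; the pipeline's defaults keep the film
  conductance ≥ 10× the enzymatic one);
* sensor response = OLS slope of i_KL versus concentration (µA/M) over
  the 50–250 µM linear range;
* optimal loading = argmax of response over the loading series, ties
  broken toward less enzyme; a still-increasing series is flagged
  unsaturated.

Defaults: n = 2 (Prussian-Blue-mediated two-electron H2O2 reduction),
A = π·(0.25 cm)² (5 mm disc), ν = 0.01 cm²/s (aqueous buffer, room
temperature), all configurable. Rotational speeds 49/100/169 rpm give
near-evenly spaced ω^{-1/2} and a design condition number ≈ 13 —
well-conditioned for a two-parameter line.

## Synthetic data

The generators produce exactly what the analysis consumes, under the
assumed error structure:

* rate assays: multiplicative Gaussian noise, CV 3% default
  (plate-reader-grade repeatability), clipped at zero; substrate designs
  log-spaced over 0.05–50 mM (plain) and 0.05–100 mM with pyruvate
  {0, 2, 10, 40} mM (inhibition); 3 replicates;
* thermal profiles: 30–70 °C in 2.5 °C steps, transition width 2 °C,
  CV 2%; pH profiles: an empirical Gaussian bell on the 4.5–9.5 grid —
  no ionization mechanism is implied;
* amperograms: three 15 s speed segments (45 s total) at 20 Hz,
  first-order settling transient with a 1 s time constant at each speed
  change (a fixture detail: only the plateaus feed the analysis),
  additive Gaussian noise with σ = 1% of the local model current
  (potentiostat-grade), sign configurable;
* sensor truths: D_lactate = 6.0e-6 cm²/s, D_H2O2 = 1.4e-5 cm²/s
  (aqueous small-molecule diffusivities), k2 = 1e-5 m/s, film
  permeability 0.05 cm/s (film conductance ~65× the enzyme term at
  100 µM, keeping the k2 inversion in its validity regime);
* the mixed-inhibition interaction factor defaults to α = 1.5: a value
  distinct from the noncompetitive degeneracy (α = 1) yet close enough
  that selection is a non-trivial statistical task.

What the generators do **not** emulate: electrode degradation and
drift, Prussian-Blue redox kinetics, oxygen-concentration dependence
(ambient O2 assumed fixed), pH-dependent rate laws beyond the empirical
bell, correlated or heteroscedastic-beyond-CV noise, and outlier
transients. Passing recovery tests therefore demonstrate correctness
of the estimators under the assumed error model, not robustness to
artifacts real instruments produce.

## Problem sizes

Recovery and power checks use the study-scale designs directly: 24–132
rate points per fit, 500 seeded simulations for selection power, 100
seeded amperogram replicates (900 samples each) for the noisy KL round
trip. The whole suite runs in well under a minute.

## Known limitations

* The k2 inversion inherits any bias in the solution Km and any film
  contribution to the KL intercept; the pipeline computes k2 only at
  the lowest loading and the generator documents its film-to-enzyme
  conductance ratio, but real films are not guaranteed to satisfy it.
* Inhibition fits use the α-parameterization of mixed inhibition;
  datasets truly generated by a two-Ki mechanism with strong asymmetry
  map onto (Ki, α) without loss, but reported Ki then refers to the
  competitive component.
* The F-test assumes independent homoscedastic Gaussian residuals;
  with multiplicative noise this holds only approximately (residual
  variance grows with the rate). At CV ≤ 3% the approximation is
  benign, as the selection-power checks show.
* `extract_steady_state` assumes the schedule's segment boundaries are
  accurate; it discards the transient by fraction, not by change-point
  detection.
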