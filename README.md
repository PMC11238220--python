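# loxsense

Enzyme-kinetic and electrochemical characterization of FMN-dependent
L-lactate oxidases (LOx) for biosensor development.

L-lactate biosensors couple a LOx to an electrode: the enzyme oxidizes
L-lactate to pyruvate, the H2O2 it releases is reduced at a mediated
(Prussian Blue) electrode, and the current reports the analyte
concentration. Picking the right enzyme requires characterizing it
twice — in solution (apparent Km, kcat, pyruvate inhibition, pH window,
thermal stability T50) and immobilized on the electrode, where a
rotating-disc electrode (RDE) lets Koutecký–Levich (KL) analysis
separate bulk mass transport from the film and enzyme contributions.
`loxsense` implements both halves as a tested, seeded pipeline, plus
synthetic-data generators that stand in for the raw plate-reader and
potentiostat measurements.

## What it computes

**Solution kinetics** (`loxsense.kinetics`)

* Michaelis–Menten fits, v = Vmax·[S]/(Km+[S]), with kcat/Km
  specificity constants;
* global fits of four inhibition rate laws (competitive,
  uncompetitive, noncompetitive, mixed with interaction factor α) and
  model selection by the extra-sum-of-squares F-test;
* relative-activity panels, pH activity windows (≥ 80% of maximum),
  and sigmoidal thermal-inactivation fits
  (activity = 100/(1+exp((T−T50)/w))).

**RDE electrochemistry** (`loxsense.electrochem`)

The recorded current is a reciprocal sum of resistances,
1/i = 1/i_mt + 1/i_film + 1/i_enz, where only the Levich term
i_mt = 0.62·n·F·A·D^{2/3}·ν^{-1/6}·C·ω^{1/2} depends on rotation, so
1/i is linear in ω^{-1/2}. From the KL regression:

* slope → analyte diffusion coefficient,
  D = [1/(0.62·n·F·A·ν^{-1/6}·C·slope)]^{3/2};
* intercept → infinite-rotation current i_KL, and with
  i_KL = n·F·A·k2·Km·C/(Km+C) the heterogeneous sensor rate constant
  k2 (m/s);
* i_KL versus concentration → sensor response (µA/M), and a loading
  sweep → the optimal amount of immobilized enzyme;
* a k2-versus-kcat ranking showing how far solution turnover predicts
  sensor performance.

**Synthetic data** (`loxsense.synthetic`) generates every input above
from seeded ground truths; `loxsense.enzymes` carries the reference
panel of eight characterized LOx enzymes (SdLOx … AvLOx) used to
parameterize the simulations.

## Worked example

```python
from loxsense.enzymes import REFERENCE_ENZYMES
from loxsense.synthetic import KineticGroundTruth, gen_inhibition_dataset
from loxsense.kinetics import fit_inhibition, fit_michaelis_menten

rec = REFERENCE_ENZYMES["AvLOx"]
truth = KineticGroundTruth(Km=rec.km_mM, kcat=rec.kcat_s,
                           inhibition_model="mixed", Ki=rec.ki_mM,
                           alpha=1.5, noise_cv=0.03, seed=11, enzyme="AvLOx")
ds = gen_inhibition_dataset(truth)

mm = fit_michaelis_menten(ds.uninhibited())
print(f"Km = {mm.Km:.2f} mM, kcat = {mm.kcat:.2f} 1/s, "
      f"kcat/Km = {mm.specificity:.0f} 1/(mM s)")

fits, sel = fit_inhibition(ds)
chosen = next(f for f in fits if f.model == sel.chosen_model)
print(f"selected: {sel.chosen_model}, Ki = {chosen.Ki:.2f} mM, "
      f"alpha = {chosen.alpha:.2f}")
```

prints

```
Km = 0.31 mM, kcat = 45.59 1/s, kcat/Km = 145 1/(mM s)
selected: mixed, Ki = 7.64 mM, alpha = 1.61
```

i.e. from a simulated assay at the AvLOx constants (Km 0.33 mM, kcat
46.26 s⁻¹, Ki 7.94 mM) with 3% noise, the fits recover the generating
parameters within their sampling error and the F-test identifies mixed
inhibition.

The full campaign for the eight-enzyme panel is the numbered scripts:

```
python analysis/01_simulate.py       # rate/thermal/pH tables + amperograms
python analysis/02_fit_kinetics.py   # Km, kcat, kcat/Km table
python analysis/03_fit_inhibition.py # Ki + inhibition-type table
python analysis/04_stability_ph.py   # T50 and pH-window tables
python analysis/05_kl_analysis.py    # D, k2, responses, optimal loadings
```

each writing its tables under `results/`. `loxsense.pipeline.run_pipeline`
exposes the same end-to-end run as one library call with a config and a
single seed driving every stochastic stage (identical config + seed ⇒
identical numeric outputs, recorded in a run manifest).

## Layout

```
src/loxsense/     library: synthetic, kinetics, electrochem, io, pipeline
analysis/         numbered drivers reproducing the characterization campaign
tests/            pytest suite (unit, property and end-to-end checks)
scripts/          acceptance script
docs/methods.md   models, defaults, numerical choices, limitations
```
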