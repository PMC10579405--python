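# mucodyn

Kinetic modeling and flow-cytometry analytics for batch co-cultures of the
human gut bacteria *Bacteroides thetaiotaomicron* (BT) and *Roseburia
intestinalis* (RI) grown with and without mucin beads.

When these two species ferment the glucose and pyruvate of WC medium, the
acids they secrete push the pH from 6.7 toward 5, and the bottle's ecology
turns on how each species copes: BT grows fastest but loses viability once
glucose is gone and the medium is acidic — unless mucin beads give it an
alternative energy source to forage — while RI survives by a diauxic shift
to consuming acetate and lactate, producing butyrate and nudging the pH
back up. Their interaction strength (the log ratio of viable counts in
co- versus monoculture) therefore changes sign along the growth curve.
`mucodyn` packages this system end to end for people who study microbial
interaction dynamics in changing environments:

* **`mucodyn.model`** — a kinetic ODE model: per species a glucose-fed
  fast state, a "slow growth mode" (mucin foraging for BT,
  lactate/acetate consumption for RI) and an inviable pool; lumped pools
  for glucose+pyruvate (G), mucin sugars (M), acetate+lactate (A),
  butyrate and other acids; algebraic pH, `pH = pH0 − c_pH·ΣSCFA`, feeding
  back on growth through per-species Hill factors (BT the more
  acid-sensitive). Growth is Monod, e.g. BT's fast state grows at
  `µ_BT·G/(K_G+G)·φ_BT(pH)`, RI's glucose growth is inhibited by mucin
  sugars, BT's mucin growth by glucose; a fixed fraction of cells
  (33% BT, 25% RI) is attached to the beads and releases mucin sugars.
* **`mucodyn.flow`** — the event-level measurement pipeline: asinh
  normalization, seeded 3-D UMAP embedding, live/inviable/debris/blank
  gating with density-proportional blank removal, supervised-UMAP +
  Mahalanobis 50-NN species assignment, and conversion of event counts to
  absolute densities (events / 10 µl × dilution).
* **`mucodyn.calibrate`** — joint least-squares fitting of the model to
  trajectories, with parameter-recovery diagnostics.
* **`mucodyn.interactions`** — interaction strengths, pH–ΣSCFA and
  attached–planktonic regressions.
* **`mucodyn.synth`** — synthetic trajectory replicates and labeled
  flow-event mixtures, so every stage is testable without any downloads.

The numbered scripts under `analysis/` run the study's analyses over the
calibrated model and write tables to `results/`; `docs/methods.md`
documents the model, its assumptions and its limitations.

## Worked example

```python
from mucodyn import ModelParams, scenario_presets, simulate

params = ModelParams()                      # calibrated defaults
runs = {name: simulate(sc, params) for name, sc in scenario_presets().items()}

t, peak = runs["BT_mono_WC"].peak("bt", "total")
print(f"BT monoculture peak: {peak:.3g} cells/ul at {t:.0f} h, "
      f"final pH {runs['BT_mono_WC'].ph()[-1]:.2f}")
print(f"RI monoculture peak: {runs['RI_mono_WC'].peak('ri', 'total')[1]:.3g} "
      f"cells/ul, pH at 24 h {runs['RI_mono_WC'].value_at('pH', 24):.2f}")
print(f"co-culture with mucin, BT planktonic peak: "
      f"{runs['co_mucin'].peak('bt', 'planktonic')[1]:.3g} cells/ul")
```

prints

```
BT monoculture peak: 1.24e+06 cells/ul at 20 h, final pH 5.05
RI monoculture peak: 7.3e+05 cells/ul, pH at 24 h 5.64
co-culture with mucin, BT planktonic peak: 1.13e+06 cells/ul
```

— BT alone peaks at ~1.2×10⁶ viable cells/µl around 20 h and acidifies the
bottle to pH ≈ 5; RI alone peaks lower with milder acidification; mucin
roughly doubles BT's co-culture peak relative to plain medium. The same
objects expose full trajectories (`.data`), planktonic/attached splits
(`.viable("bt", "attached")`) and metabolite curves (`.metabolite("Bu")`).

The classification side runs just as directly:

```python
from mucodyn.synth import make_population_spec, generate_flow_events
from mucodyn.flow import process_sample

events = generate_flow_events(make_population_spec(6.0, total_events=3000, seed=1))
blanks = generate_flow_events(
    make_population_spec(6.0, {"blank": 1.0}, total_events=600, seed=2), role="blank")
classified, counts, qc = process_sample(events, blanks, seed=7)
print(qc["category_accuracy"])   # 1.0 at 6-SD population separation
```

A `mucodyn` command-line tool wraps these steps
(`mucodyn simulate|fit|classify|interactions|synth|report`).

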