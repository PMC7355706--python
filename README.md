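# gisim

Mechanistic simulation of oral drug dissolution, supersaturation and
precipitation in a three-chamber **gastrointestinal simulator (GIS)** —
stomach, duodenum, jejunum — coupled to an open two-compartment
pharmacokinetic model that converts dissolved intestinal drug into plasma
exposure. The package targets biopharmaceutics scientists asking "what-if"
questions about a weakly basic, poorly soluble drug (BCS class 2b):
what happens to systemic exposure if the dose is taken with Coca-Cola
instead of water, or if gastric emptying is slowed?

The shipped presets describe a 10 mg immediate-release loratadine tablet
tested under four fasted-state conditions: water vs. cola as the
co-administered beverage, and a gastric-emptying half-life of 15 vs. 30 min.

## Model

**Transit and dissolution (per chamber):** first-order gastric emptying
(k_GE = ln 2 / t<sub>1/2,G</sub>) with constant gastric and duodenal
secretions (1 mL/min each), a constant 50 mL duodenum (outflow = inflow) and
an accumulating jejunum. Dissolution follows z-factor kinetics,

dX<sub>diss</sub>/dt = Z · X<sub>solid</sub> · (C<sub>s</sub>(pH) − C)₊,

with pH-dependent solubility of the weak base
C<sub>s</sub>(pH) = S₀·(1 + 10^(pKa − pH)). Precipitation in the intestinal
chambers is first-order on the supersaturated excess,
k<sub>pre</sub> · (X<sub>diss</sub> − C<sub>s</sub>V)₊, and the precipitate
is inert. Of the solid particles emptied from the stomach, a fraction
`frac` transfers downstream; the complement is an inert retained residue
(the tablet never fully disintegrates within the experiment). The degree of
supersaturation is DS = C/C<sub>eq</sub>, and buffer capacity from titration
records is β = Δn/|ΔpH|, cross-checked by the monoprotic Van Slyke equation.

**Disposition:** dX<sub>c</sub>/dt = K<sub>a</sub>·A(t) −
(K<sub>10</sub>+K<sub>12</sub>)·X<sub>c</sub> + K<sub>21</sub>·X<sub>p</sub>,
with A(t) the dissolved duodenal + jejunal amount as an open-loop forcing
(the in vitro system has no absorptive sink) and plasma concentration
C<sub>p</sub> = X<sub>c</sub>/(V/F). The disposition constants are the
arithmetic means of a packaged 12-study compilation. Exposure is summarized
as Cmax, Tmax, and trapezoidal AUC over 5–360 min.

**Estimation:** transit coefficients are fit to per-compartment
concentration–time tables by bounded least squares from multiple seeded
starts, with rates searched in log10 space and `frac` in logit space.

## Worked example

```python
from gisim import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(conditions=(1, 2, 3, 4)))
for label, r in result.conditions.items():
    m = r.exposure
    print(f"{label}: Cmax={m.cmax:.5f} ug/mL  AUC(5-360)={m.auc:.3f} ug/mL*min")
print("fold vs condition1:", result.fold_vs_first["condition4"])
```

prints

```
condition1: Cmax=0.00158 ug/mL  AUC(5-360)=0.380 ug/mL*min
condition2: Cmax=0.00244 ug/mL  AUC(5-360)=0.544 ug/mL*min
condition3: Cmax=0.00531 ug/mL  AUC(5-360)=1.307 ug/mL*min
condition4: Cmax=0.00514 ug/mL  AUC(5-360)=1.137 ug/mL*min
fold vs condition1: {'cmax_fold': 3.253..., 'auc_fold': 2.989...}
```

Condition 1 (water, fast emptying) predicts ~0.0016 µg/mL peak plasma and
0.38 µg/mL·min exposure for the 10 mg tablet; the cola/slow-emptying
scenario (condition 4) triples both metrics, because the acidic, fast-
dissolving gastric environment and the delayed acid load keep more drug in
solution once it reaches the intestine.

The same workflow is available from the shell:

```sh
gisim simulate --condition 3 --out traj.csv     # transit trajectory
gisim synth --condition 1 --seed 0 --out obs.csv  # noisy triplicate tables
gisim fit --observations obs.csv --condition 1 --out fit.json
gisim pk --conditions 1,2,3,4 --out runs/       # plasma + exposure reports
gisim reproduce-paper --out repro/              # four-condition comparison
```

Synthetic example observation tables (generated by `gisim.synthetic`, not
measured data) for all four conditions are committed under `fixtures/`.

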