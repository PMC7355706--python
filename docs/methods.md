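# Methods

## Scope

`gisim` implements the in-silico chain of a gastrointestinal-simulator (GIS)
study of loratadine: a mass-transport ODE model of drug transit, dissolution
and precipitation through stomach → duodenum → jejunum; least-squares
estimation of the kinetic coefficients against concentration–time data; and
an open two-compartment disposition model that converts dissolved intestinal
drug into plasma concentration and exposure metrics. Wet-lab concerns
(HPLC analytics, disintegration testing, instrument control) and in-silico
property prediction are out of scope.

## Transit model

State per chamber: fluid volume, solid drug, dissolved drug, precipitated
drug (µg). Governing equations:

- **Stomach.** dV_s/dt = k_sec_s − Q_s with Q_s = k_GE·V_s and
  k_GE = ln2/t_half; if V_s ever falls to the 5 mL residual floor, outflow
  drops to match secretion and the volume pins there (with the default
  1 mL/min secretion the floor is never reached — the volume settles at
  k_sec/k_GE ≈ 21.6 mL for t_half = 15 min). Dissolved drug leaves with the
  fluid at specific rate Q_s/V_s. Solid particles leave at the same specific
  rate, but only a fraction `frac` continues into the duodenum; the
  complement accumulates in an inert "retained residue" pool representing
  the never-disintegrated part of the tablet. The residue and the
  precipitate pools are inert over the simulated horizon: allowing
  redissolution would make the precipitation rate and the dissolution
  coefficient jointly unidentifiable from concentration data.
- **Duodenum.** Constant 50 mL: outflow Q_dj equals inflow Q_s + k_sec_d.
  Receives gastric dissolved and (frac-scaled) solid drug, dissolves solid
  by z-factor kinetics, precipitates the supersaturated excess at first
  order (k_pre_d), and passes both dissolved and solid drug downstream at
  specific rate Q_dj/V_d.
- **Jejunum.** Accumulates all duodenal outflow (no exit), with its own
  dissolution coefficient and precipitation rate k_pre_j.

Dissolution flux is Z·X_solid·(C_s − C)₊ and precipitation flux
k_pre·(X_diss − C_s·V)₊. The positive-part driving forces mean nothing
dissolves above saturation and nothing precipitates below it; a plain
first-order loss on total dissolved mass would drain subsaturated solutions,
which is unphysical.

Solubility follows the Henderson–Hasselbalch curve of a monobasic weak base,
S(pH) = S0·(1 + 10^(pKa−pH)), with optional measured-solubility overrides
interpolated linearly in pH. The default drug preset uses the measured
literature constants pKa 5.3 / logP 3.9; an alternative preset carries the
in-silico predicted pair (pKa 3.83) because both circulate for this
compound and the choice is data, not code.

Each condition prescribes per-chamber pH time courses as piecewise-linear
profiles. Water conditions hold the stomach at pH 2.0 and both intestinal
chambers at 6.5. Cola conditions hold the stomach at pH 2.48 and dip the
duodenal pH to the observed minima (3.27 fast-emptying, 4.25 slow-emptying);
the timing of the dip is not published, so the presets place the minimum at
15 min with linear recovery to 6.5 by 60 min, and the profiles are ordinary
config fields for anyone who wants a different shape.

Numerics: LSODA with rtol 1e-8, atol 1e-10 µg (fitting uses rtol 1e-6 for
speed), dense output sampled onto the caller's grid; concentrations are
defined as 0 below a 0.1 mL volume epsilon (the initially empty jejunum).
Mass and volume balance hold to ≤1e-6 relative at all output times by
construction and are enforced in the test suite.

## Calibrated defaults

Two constants the source study does not publish had to be set once,
and are documented here as the package's calibration:

- **z_unit_scale = 2×10⁵.** The tabulated dissolution coefficients
  (~1e-11 mL/µg/min) are numerically inoperable on the µg/mL scale of this
  system — they imply dissolution half-lives of years. A single multiplier
  applied uniformly to all twelve tabulated Z values preserves their printed
  relative ordering while making the kinetics operable.
- **S0 = 3.0 µg/mL.** The intrinsic solubility of neutral loratadine was
  measured in the study but never tabulated; the default sits in the
  literature low-µg/mL range.

The pair was chosen on a coarse grid to minimize the worst relative
deviation of the condition-1 pipeline's exposure (AUC 5–360 min, Cmax) from
the study's published simulated values (0.35 µg/mL·min, 0.0017 µg/mL); the
shipped defaults land within ~9% on both. No other constant was tuned.

## Disposition model and coupling

dX_c/dt = K_a·A(t) − (K_10+K_12)·X_c + K_21·X_p, dX_p/dt = K_12·X_c −
K_21·X_p, with the tabulated h⁻¹ constants converted to min⁻¹ and plasma
concentration X_c/(V/F). A(t) is the dissolved duodenal + jejunal amount;
gastric drug is not absorbable. Coupling is open-loop — absorption does not
deplete the luminal series — because the in vitro system has no absorptive
sink and closing the loop would double-count. Disposition constants are
pooled as arithmetic means of the packaged 12-study table (the pooled row
reproduces the published means, e.g. K_a 0.846 h⁻¹, V/F 1198 L).

To drive the 360-min plasma simulation, the transit ODEs are integrated over
the full horizon with pumps and secretions assumed to keep running and each
pH held at its final value beyond the 60-min in vitro window. The
alternative — freezing the luminal state at 60 min and decaying it — was
rejected because the slow-emptying conditions still hold ~107 mL of gastric
fluid (and drug) at 60 min, and truncating their input would penalize
exactly the scenarios whose delayed delivery is the object of study.
`simulate_plasma` still supports hold-with-first-order-decay extrapolation
for luminal series shorter than the horizon (e.g. measured data).

Exposure metrics are Cmax/Tmax over the full grid and trapezoidal AUC over
a window, default 5–360 min to match the published metric. Bioequivalence
is a <20% percent-difference check per metric; scenario comparison reports
Cmax and AUC ratios.

## Parameter estimation

Bounded trust-region least squares (`scipy.optimize.least_squares`, TRF) on
residuals between simulated and observed mean concentrations, optionally
weighted by 1/SD with a floor of 5% of each compartment's maximum mean so
zero-SD points cannot dominate. Rates are fit in log10 space (the tabulated
values span ten decades), `frac` in logit space. Multi-start: the supplied
initial guess (or the bounds centroid) plus seeded scrambled-Sobol draws
inside the transformed box, best loss wins; default 8 starts, deterministic
given the seed. Finite-difference steps for the Jacobian are set to 1e-4 in
the transformed coordinates — far above the ODE-solver noise floor, which
otherwise corrupts the gradient and strands the optimizer on shallow valley
points.

Identifiability is structural, not merely statistical: in a scenario whose
intestinal chambers stay supersaturated, the intestinal dissolution
coefficients and `frac` leave no trace in concentration data (the driving
force is clamped at zero), and near-zero precipitation rates are only ever
recoverable as "effectively zero". The recovery experiments in the test
suite therefore use two designed synthetic truths: a water-like scenario
identifying {z_s, k_pre_d, k_pre_j}, and an acid-dip scenario whose
transient intestinal pH drops make {z_s, z_d, z_j, frac} identifiable.
Noise-free recovery is exact to ≪1%; under 5%-CV triplicate noise the
seed-averaged rate estimates stay within 25%, and zero-precipitation truths
are recovered at the k_pre ≤ 1e-3 min⁻¹ boundary.

## Synthetic data generator

Emulates the study's triplicate sampling: simulate the truth, draw
`replicates` multiplicative-Gaussian realizations per time point and chamber
(default CV 5%, clipped at zero), report mean ± SD. Clipping introduces a
slight positive bias at near-zero concentrations. The default schedule
samples every 2.5 min to 20 min, then every 10 min to 60 min. What the
generator does **not** emulate: analytical (HPLC) calibration drift,
pH-measurement error, replicate-to-replicate differences in tablet
disintegration, or any correlation between chambers — so passing recovery
tests demonstrate correctness of the estimation machinery under the model's
own assumptions, not robustness to real-world model misspecification.
Titration records are generated inversely from a target buffer capacity,
with optional volume noise (multiplicative, keeping the β estimator
unbiased).

## Known limitations

- The study's appendix ODEs are not public; this is a reconstruction from
  the described Matsui-style mass transport analysis. The printed
  coefficient set under this reconstruction makes the two cola scenarios
  nearly equivalent (both precipitate negligibly), so the simulated
  fast-emptying cola condition slightly outperforms the slow one, whereas
  the study's measurements put the slow-emptying cola condition highest.
- The simulated condition-1 plasma profile rises throughout the 360-min
  window (the luminal dissolved amount plateaus rather than declining), so
  its Cmax/AUC ratio is ~0.0041 min⁻¹ against ~0.0049 implied by the
  published simulation; the comparison against the clinical reference
  product lands at ~27% on AUC, outside the 20% bioequivalence bound the
  study reports.
- Single-drug, fasted-state, fixed secretion rates; no micellar
  solubilization, no CO₂/hydrodynamic effects, no metabolite kinetics, no
  inter-individual variability.
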