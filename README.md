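# qsmrim

In-silico validation of paramagnetic rim lesion (PRL) detection on
quantitative susceptibility mapping (QSM) versus high-pass-filtered (HPF)
phase MRI.

## The problem

Chronic active multiple sclerosis lesions carry a rim of iron-laden
microglia/macrophages. That rim is an imaging biomarker — hyperintense on
QSM, hypointense on HPF phase — but the two modalities disagree: phase
imaging flags more lesions as rim-positive than QSM does, and histology
shows many of those extra calls are iron-negative. The physics explains
why. A uniformly magnetized sphere (a solid demyelinated core, no iron)
has zero Lorentz-corrected internal field and an external dipole field

    ΔB/B0(r, θ) = (Δχ/3)(a/r)³ (3cos²θ − 1),    r > a,

which is *identical* to the external field of a spherical shell (an iron
rim) of matched total moment Δχ·(a_out³ − a_in³). High-pass filtering then
nulls the uniform interior phase and leaves a rim-shaped band at the
boundary of both, so filtered phase cannot tell a solid core from a true
iron rim from outside — while dipole deconvolution (QSM) recovers the
interior susceptibility distribution and can.

This package builds that argument as a testable pipeline for methods
researchers: lesion susceptibility phantoms with known iron-rim ground
truth, k-space dipole forward simulation of a 3 T multi-echo gradient-echo
acquisition (0.5 mm isotropic, TE = 3.4 + 5.6·k ms, 8 echoes), bit-faithful
HPF phase reconstruction (2D circularly symmetric Hanning low-pass,
complex division), simplified regularized dipole inversion (TKD and a
conjugate-residual Tikhonov total-field inversion), an automated rim
reader, and the diagnostic-accuracy and rater-agreement statistics
(sensitivity/specificity/PPV/NPV/accuracy, Fleiss κ, Cohen κ,
Landis–Koch bands, majority vote).

## Worked example

```python
from qsmrim.experiment import ExperimentConfig, run_experiment

config = ExperimentConfig(
    n_per_class=1,
    classes=("solid", "rim"),
    grid_shape=(64, 64, 64),
    filter_radius=16,
    lesion_params={"core_radius": (2.5, 3.5), "center_jitter": 1.5},
    seed=7,
)
bundle = run_experiment(config)
cols = ["lesion_id", "iron_rim_status", "qsm_z", "qsm_call", "phase_z", "phase_call"]
print(bundle.calls[cols].round(2).to_string(index=False))
```

prints

```
 lesion_id iron_rim_status  qsm_z qsm_call  phase_z phase_call
L000_solid           iron-  -2.98     rim-    -0.93       rim-
  L001_rim           iron+  11.69     rim+    -4.29       rim+
```

`qsm_z` and `phase_z` are boundary-vs-core contrasts in units of the
robust background noise. The iron rim is strongly hyperintense on QSM
(z = +11.7 → rim+) and its halo is hypointense on filtered phase
(z = −4.3 → rim+). The solid, iron-negative lesion shows *no* QSM rim
(z negative: core brighter than boundary) but still carries a hypointense
phase halo of the same shape as a true rim's (z = −0.9) — weaker only
because its susceptibility moment is smaller, which is exactly the
confound: on phase the two lesion types differ in degree, not in kind.

Diagnostic metrics from any calls-vs-truth table:

```python
from qsmrim.diagnostics import ContingencyTable, diagnostic_metrics
m = diagnostic_metrics(ContingencyTable(tp=10, fp=0, fn=1, tn=21))
print(m.sensitivity_pct, m.specificity_pct, m.ppv_pct, m.npv_pct, m.accuracy_pct)
# 91 100 100 95 97
```

A CLI mirrors the library: `qsmrim simulate`, `qsmrim reconstruct`,
`qsmrim score`, `qsmrim evaluate`, `qsmrim run` (see `qsmrim --help`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end study from scratch: it generates the
default seeded 32-lesion cohort (8 each of solid, full-rim, partial-rim and
veined lesions), simulates the multi-echo acquisition at SNR 50,
reconstructs both modalities, scores and classifies every lesion, and
writes the JSON report to `--out`, logging the computed contingency tables
and metrics to stderr.

See `docs/methods.md` for the model, parameter choices, numerical details
and known limitations.
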