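# upticksim

Stochastic model of the transient rise-and-fall — the **uptick** — in basal
*comK* promoter activity in *Bacillus subtilis*, together with the
dual-reporter noise analysis and the two-channel single-cell competence
classification pipeline that accompany it.

## The science

Entry into genetic competence is a stochastic cell-fate decision gated by a
"window of opportunity": the basal firing rate of the *comK* promoter rises
as a culture approaches stationary phase, peaks near the growth transition
T₀ (≈ 2.25 h after inoculation in the assay conditions modelled here), and
then shuts down. The model explains this uptick with two regulators acting
on top of a global core-promoter activity g(t):

- **Rok**, a constitutively present repressor, binds a high-affinity site
  (K_D ≈ 15 nM) overlapping the Spo0A binding site *A2*, plus an auxiliary
  site (K_D ≈ 50 nM).
- **Spo0A~P** accumulates steadily after the growth transition (the model's
  clock). At low concentration it binds activation sites *A1–A3*
  (K_D ≈ 50 nM), anti-repressing by competing Rok off the *A2* region and
  boosting transcription α-fold per occupied site; at higher concentration
  it occupies repression sites *R1–R2* (K_D ≈ 125 nM) and shuts the
  promoter down. Because the A sites bind more tightly than the R sites,
  activation precedes repression and the product

  rate(t) = k_tx · g(t) · α^{nA} · ρ_Rok^{nRok} · ρ_R^{nR}

  traces out the uptick.

The network (binding/unbinding at every site, transcription, mRNA decay,
Spo0A~P production) is simulated exactly with Gillespie's stochastic
simulation algorithm; time-dependent drives are handled by capping waiting
times at 0.01 h. Rate coefficients not fixed by gel-shift measurements are
calibrated so that ensemble amplitude ratios between regulator knockouts
reproduce the measured fold-changes (≈9-fold loss without *spo0A*, ≈5-fold
gain without *rok*, recovery to ≈60 % of the Δ*rok* level in the double
knockout, ≈30 % *spo0A*-dependence in the A123 site mutant, and about one
transcript per cell at the peak).

Two analyses sit on top of the simulator:

- **Dual-reporter noise decomposition** — two identical *comK* promoters in
  one cell share the Spo0A~P and Rok pools; the Pearson correlation of
  their transcript counts across an ensemble measures how much of the
  expression noise is extrinsic (shared) versus intrinsic.
- **Single-cell cytometry pipeline** — calibrates a competence threshold on
  a *comK*-CFP reporter from a late-time *comG*-YFP population, classifies
  cells, histograms the competent fraction against a YFP reporter of
  Spo0A~P, and tests the drop in competence probability beyond a YFP
  boundary with a two-proportion z-test. A synthetic-data module generates
  per-cell intensity tables with the planted structure (autofluorescence
  floor 12–16 a.u., threshold 36 a.u., window-shaped competence
  probability) so the whole pipeline is testable without any measurement.

## Worked example

```python
import numpy as np
from upticksim import (ModelParams, strain_preset, build_network,
                       run_ensemble, mean_rate_curve, peak_amplitude,
                       amplitude_ratio)

params = ModelParams()                      # calibrated defaults
curves = {}
for label in ("wt", "d_spo0A"):
    net = build_network(strain_preset(label), params)
    ens = run_ensemble(net, n_runs=1000, t_end=6.0, base_seed=1)
    curves[label] = mean_rate_curve(ens, bin_width=0.1)

peak, t_peak = peak_amplitude(curves["wt"])
print(f"wt peak rate {peak:.2f} events/h at t = {t_peak:.2f} h")
print(f"peak mean mRNA {curves['wt'].mrna_mean.max():.2f} per cell")
print(f"wt / d_spo0A amplitude ratio {amplitude_ratio(curves['wt'], curves['d_spo0A']):.1f}")
```

prints

```
wt peak rate 4.14 events/h at t = 2.05 h
peak mean mRNA 1.05 per cell
wt / d_spo0A amplitude ratio 8.9
```

i.e. the wild-type promoter fires about four times per hour at the top of
the uptick (just before T₀ = 2.25 h), carries about one transcript per
cell there, and loses roughly nine-fold of its amplitude when *spo0A* is
deleted.

The same runs are available from the shell:

```bash
upticksim compare --strains wt,d_spo0A --runs 1000 --seed 1 --out out/
upticksim correlate --runs 2000 --seed 1 --out out/
upticksim synth --cells 10000 --seed 0 --calibration --out out/
upticksim cytometry --cells out/cells.csv --boundary 120 --out out/
```

Every command writes CSV outputs plus a `manifest.json` echoing the full
configuration and seeds; identical configurations give byte-identical
outputs.

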