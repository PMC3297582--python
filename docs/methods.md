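# Methods

## Model

One cell contains one (or, for the noise analysis, two identical) copies
of the *comK* promoter, a constant pool of the repressor Rok, and a
growing pool of phosphorylated Spo0A (written OA~P below). Time is hours
since inoculation; with the cell volume fixed at 1.66 fL, 1 nM corresponds
to one molecule per cell to within 0.1 %, so dissociation constants in nM
double as molecule counts.

### Promoter sites

Each promoter copy carries

| site | ligand | K_D (nM) | effect when occupied |
|---|---|---|---|
| A1, A3 | OA~P | 50 | transcription ×α |
| A2 | OA~P **or** Rok (competition) | 50 / 15 | ×α or ×ρ_Rok |
| RokAux | Rok | 50 | ×ρ_Rok |
| R1, R2 | OA~P | 125 | ×ρ_R |

The K_Ds are gel-shift nominal values; the R-site measurement spans
100–150 nM and the midpoint 125 nM is used. A2 is a single lattice
position: OA~P and Rok exclude each other there, which is the model's
anti-repression mechanism, while Rok at the auxiliary site is never
displaced — OA~P bound at A sites raises transcription multiplicatively
without removing that repressor.

### Transcription propensity

For one promoter copy,

    a_tx = k_tx · g(t) · α^nA · ρ_Rok^nRok · ρ_R^nR

with nA the number of OA~P-occupied A sites, nRok the Rok-occupied sites,
nR the OA~P-occupied R sites. The multiplicative form makes joint
Rok + OA~P repression stronger than either alone. An alternative
`activation_mode="all_or_none"` (boost α³ only with all three A sites
occupied) is exposed; the default is the per-site boost.

### Drives

`g(t)` is the global core-promoter activity: a Gaussian ramp (σ = 0.8 h)
from a floor of 0.1 up to exactly 1 at t₀ = 2.25 h, then a two-exponential
decline (fast rate 2 h⁻¹, slow "shoulder" component of weight 0.25 at
0.25 h⁻¹) toward a late floor of 0.02. Any smooth unimodal form with a
pre-growth floor, a peak at t₀ and a shouldered decline would serve; this
one was chosen for having few, interpretable parameters. `h(t)` drives
*spo0A* transcription: it follows the same rise but stays at its plateau
after t₀, so the OA~P pool keeps accumulating — the clock that first
activates (A sites, lower K_D) and later represses (R sites, higher K_D).
Phosphorylation is not modelled separately: the phosphorelay is taken as
fast, so all produced Spo0A counts as OA~P.

### Reactions

Per promoter copy: OA~P binding/unbinding at A1, A2, A3, R1, R2; Rok
binding/unbinding at the A2-overlapping site and the auxiliary site;
transcription; first-order mRNA decay (k_deg = 4 h⁻¹, a ~10 min
half-life). Globally: OA~P production `oap_rate0 · h(t)` and slow decay
(0.05 h⁻¹). Binding on-rates are k_on · mult with k_on = 20 molecule⁻¹h⁻¹
and `mult` the strain's per-site affinity multiplier; off-rates are
k_on · K_D, so equilibria depend only on the measured K_Ds while site
relaxation (≲ seconds) stays far faster than the hour-scale drives
(quasi-equilibrium). k_on is not measured; 20 molecule⁻¹h⁻¹ keeps the
quasi-equilibrium property at a few tens of thousands of binding events
per run. Rok is a conserved pool ("constant amount"): free copies drop
while bound.

### Strains

Presets: `wt`/`d_comK` (the baseline; the ComK positive-feedback loop is
never modelled, so the wild-type promoter configuration corresponds to the
comK-null reporter strain), `d_rok`, `d_spo0A`, `d_rok_d_spo0A`, single-
and triple-A-site mutants, R-site mutants. Knockouts remove the species
and all their reactions. Two mutation conventions matter:

- Mutating A2 also destroys the overlapping high-affinity (15 nM) Rok
  site; the residual ~50 nM Rok binding seen with A2-mutant probes is
  attributed to the auxiliary site, which all strains retain.
- A-site point mutations retain 20 % affinity (`RESIDUAL_A_AFFINITY`,
  i.e. K_D × 5). This residual is what lets deleting *spo0A* in the A123
  triple mutant still cost ~25–30 % of the amplitude, as observed; with
  the sites fully destroyed the knockout could only raise expression
  (by relieving R1/R2 repression), contradicting the measured decrease.
  R-site mutations are modelled as complete (multiplier 0).

## Calibration of the default rate coefficients

The K_Ds are fixed by measurement; k_tx, α, ρ_Rok, ρ_R, the Rok copy
number and the OA~P production scale are not. `calibrate_defaults` fixes
them against the measured amplitude relations using a deterministic
mean-field oracle (quasi-equilibrium occupancies, independent sites, exact
ODE for the OA~P pool): a grid search keeps points whose mean-field peak
ratios satisfy, within ×1.5,

- wt / Δspo0A ≈ 9,
- Δrok / wt ≈ 5,
- ΔrokΔspo0A ≈ 60 % of Δrok,
- ≈ 30 % decrease on deleting *spo0A* in the A123 mutant,

requires the qualitative amplitude ordering Δrok > A2 > wt > A123 >
Δspo0A with ≥ 10 % separation (so the ordering survives ensemble sampling
noise), minimises the worst relative deviation among the satisfying
points, and finally rescales k_tx so the wild-type peak mean mRNA is 1
per cell. The winner — α = 2.9, ρ_Rok = 0.02, ρ_R = 0.2, 90 Rok copies,
oap_rate0 = 800 h⁻¹, k_tx = 7.356 h⁻¹ — is frozen as the shipped default,
and a test asserts the search reproduces it. Stochastic ensembles under
these defaults land within ~5–25 % of the mean-field targets (site–pool
correlations that mean-field ignores account for the drift), all inside
the ×1.5 calibration contract.

## Stochastic simulation

Gillespie's direct method over the compiled reaction arrays (numba).
Time-dependent propensities are handled by capping every exponential
waiting time at Δt_max = 0.01 h and redrawing with refreshed propensities;
since the drives vary on ~1 h scales the bias is negligible — the test
suite checks that halving Δt_max moves driven ensemble means by < 1 %,
and that autonomous networks reproduce the analytic immigration–death and
telegraph stationary distributions. Snapshots are taken on a 0.05 h grid
(≥ 20 points across the ~1 h uptick). Runs are seeded `base_seed + i`, so
ensembles are reproducible and order-independent; identical inputs give
bit-identical trajectories.

"Amplitude" of a strain is the peak of the ensemble-mean transcription
event rate (events per bin ÷ bin width ÷ runs, 0.1 h bins), smoothed with
a 3-bin moving average before peak extraction to suppress binning noise;
curves with fewer than six bins are taken raw, and ties break toward the
earliest time. The luciferase observable maps to this event rate — light
output tracks the instantaneous transcription rate, not accumulated
product — while the mean mRNA count is reported alongside for the
transcripts-per-cell scale. `decay_halftime` is the linearly interpolated
time after the peak at which the rate first reaches half-peak (censored at
the horizon).

## Noise analysis

A two-promoter cell duplicates every site and mRNA species while sharing
the OA~P and Rok pools and the drives. At each requested timepoint
(default t₀ − 0.5, t₀, t₀ + 0.5, t₀ + 1 h) the per-run snapshot counts of
the two mRNA species are paired across the ensemble and summarised by
Pearson's r (the dual-reporter convention); a series with zero variance
makes the correlation undefined, not zero. Under the calibrated defaults
the correlation stays near zero — transcript noise is intrinsic — and a
test demonstrates the mechanism: in a regime with a small, slowly
accumulating OA~P pool the correlation is substantial, and freezing the
pool at a fixed count collapses it to the independent baseline.

## Cytometry pipeline

- `calibrate_threshold`: competent fraction = proportion of late-time
  cells above the comG-YFP cutoff (default 50 a.u.); threshold = the
  nearest-rank (1 − fraction) upper quantile of the early CFP
  distribution. Degenerate calibrations (fraction 0 or 1) raise.
- `classify_competent`: strictly greater than threshold. Both conventions
  (strict inequality, nearest-rank quantile) are fixed for bit
  reproducibility.
- `binned_competence_fraction`: percent competent per YFP bin; empty bins
  are flagged, not zero.
- `boundary_proportion_test`: pooled two-proportion z-test, two-sided. A
  z-test is the standard well-defined test for equality of two
  proportions (a t-test on two proportions is not otherwise defined);
  Fisher's exact test is computed as a cross-check and reported as the
  headline p-value whenever any contingency cell is below 5. The YFP
  boundary itself is an analyst input (it was placed by inspection in the
  source data); `boundary_scan` reports the proportion profile over
  candidate boundaries.

## Synthetic single-cell data

`generate_cells` draws YFP as uniform(12, 16) autofluorescence plus a
log-normal extrinsic component (μ = 4.1, σ = 0.6 on the log scale), turns
each cell competent with probability given by a raised-cosine window over
YFP (default support 25–160 a.u.) rescaled so the expected competent
fraction hits the target (default 13.3 %; an unreachable target raises
with the achievable maximum), and draws CFP from either a truncated
log-normal strictly above the planted 36 a.u. threshold (competent) or
background plus half-normal basal noise strictly at or below it. The exact
separation at the threshold makes ground-truth labels recoverable and the
planted false-positive rate of threshold classification exactly zero. The
basal scale (16 a.u.) and the competent CFP parameters (μ = 3.65,
σ = 0.45) were chosen to put substantial probability density on both
sides of the threshold, so the calibration quantile transfers with ~1 a.u.
granularity at 10⁴ cells. `generate_null_cells` keeps the marginals but
makes competence independent of YFP — the null for the proportion test's
type-I error. `generate_calibration_tables` emulates the two-timepoint
calibration experiment, giving the late table a comG-like YFP channel.

What the generator does **not** emulate: temporal single-cell
trajectories, segmentation artefacts, channel bleed-through, or any
correlation between CFP and YFP beyond the planted window — so passing
tests certify the pipeline's statistics, not robustness to imaging
systematics.

## Problem sizes

Defaults throughout are sized for a single CPU: 1000-run ensembles for
amplitude comparisons (ratio standard errors of a few percent), 2000 runs
for the dual-promoter correlation, 10⁴ cells for cytometry recovery, 10³
simulated tables for the type-I-error check. Amplitude ratios are stable
to < 15 % down to a few hundred runs.

## Known limitations

- The ComK positive-feedback loop, downstream competence genes and the
  phosphorelay are outside the model; OA~P accumulation is an effective
  schedule, not a mechanistic phosphorelay model.
- Mean-field calibration ignores site–pool correlations, so stochastic
  ratios sit a few tens of percent off the mean-field targets (within the
  stated ×1.5 contract).
- The functional form of g(t) is a modelling choice constrained only by
  shape properties (floor, peak at t₀, shouldered decline).
- Minor regulators (CodY, AbrB, DegU, SinR) are not modelled; the
  residual A-site affinity stands in for whatever minor OA~P activation
  component survives the A123 mutations.
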