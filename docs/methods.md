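# Methods

## Calibration model

Cytosolic [Ca²⁺] is recovered from aequorin photon counts through the
cubed-occupancy model `L/Lmax = ((1 + K_R·Ca)/(1 + K_TR + K_R·Ca))³`,
inverted in closed form as `Ca = (f·(1+K_TR) − 1)/(K_R·(1 − f))` with
`f = (L/Lmax)^{1/3}`. The inversion is exact, which the forward/inverse
round-trip property pins to ~1e-15 relative error over [10⁻⁸, 10⁻⁴] M.

**Constants.** K_R = 7.23×10⁶ M⁻¹ and K_TR = 120 are the classical
aequorin calibration values; they are not measured by this package and are
overridable via `CalibrationConstants` or the `[calibration]` TOML section.
Every quantitative claim the test suite makes is a round-trip or recovery
property that holds for any positive constants, provided simulator and
calibrator share them.

**Lmax convention.** Because aequorin is irreversibly consumed, the
denominator is time-dependent: Lmax at bin *i* is λ_sat times the remaining
background-corrected counts from bin *i* to the end of the record. The
terminal Triton + 10 mM Ca²⁺ discharge guarantees the remaining integral
counts all surviving photoprotein. λ_sat (the consumption rate constant at
saturating Ca²⁺, default 1 s⁻¹) cancels between simulator and calibrator —
an explicit invariance test doubles it in both and verifies sub-1% change
in recovered Ca²⁺. The alternative fixed-total-integral convention is not
offered: with consumption it systematically underestimates late-record
Ca²⁺, and the remaining-integral form is the one the round-trip properties
validate.

**Validity flags.** Four conditions invalidate a bin rather than emit a
misleading concentration: (i) `below-domain` — f ≤ 1/(1+K_TR), formally
Ca ≤ 0, clamped to 0; (ii) `saturated` — f ≥ 0.999; (iii) `lmax-exhausted`
— fewer than 100 counts remain in the denominator, so the ratio is shot-
noise dominated (end of record); (iv) also flagged `saturated` — a bin that
consumes more than 5% of the remaining quanta, where the rate-based L/Lmax
estimate breaks down. In practice (iv) only ever triggers inside the
terminal discharge, which is a calibration maneuver and excluded from
feature extraction anyway. Negative background-corrected counts clamp to 0.

## Synthetic-data generator

The generator is the forward model of the same physics plus a
phenomenological Ca²⁺ trajectory:

* **Trajectory.** Baseline during `pre`; an instantaneous step to the
  reported plateau during `external_ca` (only plateau values are reported
  for this phase); exponential relaxation toward `rest_ca` during the 90 s
  Ca²⁺-free wash; during `permeabilized`, rest plus one or two release
  pulses; a saturating 10 mM step during `discharge`. Default segment
  durations are 60/120/90/600/60 s at 1 s bins, matching the standard
  perfusion protocol (2 min external Ca²⁺, 90 s Ca²⁺-free).
* **Release pulse.** Each component is
  `g(t) = (1 − e^{−t/τ_r})^m · e^{−t/τ_d}`, peak-normalised to 1 at its
  time-to-peak so that `amplitude` and `time_to_peak_s` are exact. The
  onset power m was introduced after the pure difference-of-exponentials
  (m = 1) proved unable to reproduce the observed first-derivative
  phenomenology: a two-exponential pulse has its steepest rise at t = 0,
  so every component's derivative maximum collapses onto the
  permeabilization instant and a biphasic transient shows a single
  derivative hump. A delayed sigmoidal onset (m ≈ 40 for the slow
  component) is what separates the fast and slow humps, as observed in
  derivative insets of real recordings. The peak time is closed-form,
  `t* = τ_r·ln((m·τ_d + τ_r)/τ_r)`, and `rise_tau_for_peak` inverts it so
  presets state time-to-peak directly; inconsistent (τ_r, τ_d, m,
  time-to-peak) combinations are rejected at half-bin tolerance.
* **Photon counting.** Per bin, occupancy factor f(Ca), remaining-pool
  decay `N_{i+1} = N_i·e^{−λ_sat·f·Δt}`, expected counts
  `η·N_i·(1 − e^{−λ_sat·f·Δt})` (η = detection efficiency, default 1, kept
  only to test that it cancels in L/Lmax), Poisson-distributed observed
  counts plus optional background (default 0; dark counts are not
  modelled). The telescoping sum conserves quanta exactly. The seed is
  mandatory — simulated records are reproducibility contracts.
* **Default photon budget.** N₀ = 10⁸ detectable quanta. At that budget a
  1.3 µM peak produces ~5×10⁴ counts/bin (0.4% shot noise) and a 50 nM
  rest ~140 counts/bin (~8% shot noise per bin, averaged over a 10 s rest
  window and replicates).

**Presets.** Four parameter bundles reproduce the published strain
phenotypes; concentrations follow the reported tables (wild-type peak
1.33 µM near 140 s with fast/slow components at 50 s and 2 min 20 s;
α-synuclein rest 0.29 µM, peak 2.07 µM at 75 s with faster decay; pmc1Δ
fast-component-only peak 0.94 µM; vcx1Δ low rest 0.05 µM, biphasic).
Wild-type rest is set to 0.05 µM rather than a literal zero: reported
wild-type rest values are means scattering around zero, a strictly zero
ground truth makes relative recovery error ill-defined, and 50 nM is the
textbook resting cytosolic Ca²⁺ — well inside the reported SD. The
generator models photon-counting noise only; it does not emulate
coverslip-to-coverslip biological variability, pH/Mg²⁺ effects on aequorin
kinetics, or perfusion transients. Passing recovery tests therefore
demonstrate correctness of the calibration and feature chain under
counting statistics, not robustness to biological scatter.

## Transient features

Rest [Ca²⁺] is the mean over the final 10 s of the Ca²⁺-free segment (the
window length is a package choice: short enough to sit after the decay,
long enough to average counting noise). Peak [Ca²⁺] is the maximum valid
concentration in the permeabilized segment — the discharge is excluded.
The decay half-time is the first time after the peak at which the trace
falls to rest + (peak − rest)/2.

The fast/slow decomposition smooths the permeabilized segment with an
11 s moving average, takes centred differences (one-sided at the
endpoints), and finds positive local maxima of the derivative with
prominence ≥ 15% of the derivative maximum and pairwise separation ≥ 30 s,
truncated to the two largest. Two components classify the transient
biphasic, one quasi-monophasic, none (flat trace) as `none`. No numeric
criterion for this classification exists in the literature the pipeline
follows; the derivative-peak rule with exposed thresholds is this
package's operationalisation, and the thresholds are config-overridable.

## Growth and qPCR

t₅₀ is the first time the replicate-mean OD₆₀₀ curve crosses
`od_min + (od_max − od_min)/2`, linearly interpolated between bracketing
samples; `od_min` is the minimum of the mean curve, making t₅₀ robust to
the inoculation OD (~0.01). First-crossing (not nearest-crossing) resolves
non-monotone noisy curves; curves that never reach the half level raise
`GrowthIncompleteError`. A `log_scale` switch applies the same rule to
log-OD as a sensitivity variant — half-maximal OD on the linear scale is
the primary definition. When replicates are labelled, per-replicate t₅₀
values are aggregated as mean ± SD; otherwise the mean-curve t₅₀ is
reported. Δt₅₀ is the signed difference in hours (positive = slower).

qPCR ratios use the efficiency-corrected (Pfaffl) formula
`E_target^ΔCq(target) / E_ref^ΔCq(ref)` with `E = 1 + %E/100` and
`ΔCq = mean Cq(calibrator) − Cq(sample)`, so higher expression gives a
ratio above 1. Replicates are unpaired: each replicate's ΔCq is taken
against the calibrator mean. The condition mean ratio is computed from
condition-mean Cq values (making the calibrator exactly 1 and the
noise-free round trip exact); the SD is the spread of per-replicate
ratios. Conditions with no detectable target Cq are reported
non-detectable. Default efficiencies are the PMC1/ACT1 assay values
(85% / 91%).

## Statistics

Unpaired two-sided t-tests (Student pooled-variance by default, Welch
optional) and one-way ANOVA with Bonferroni posttests accept raw values or
(mean, SD, n) summaries; the two paths are algebraically identical, which
the suite checks to 1e-12. Posttests use the pooled within-group mean
square with df = N − k and `p_adj = min(1, m·p)` where m is the size of
the declared comparison family — the family is an explicit input because
published tables rarely state it, and with k = 2 and m = 1 the posttest
reduces exactly to Student's t. Star labels: ns P > 0.05, `*` ≤ 0.05,
`**` ≤ 0.01, `***` ≤ 0.001 (inclusive at 0.0001), `****` strictly
< 0.0001. Two zero-variance groups with equal means give p = 1 by
convention; with different means the result is flagged degenerate.

## Problem sizes and numerical choices

The recovery studies run 50 seeded simulations per preset at N₀ = 10⁸ on
the 930-bin default protocol, 100 noisy growth curves, and 20,000
vectorised null t-tests — sizes chosen to make Monte-Carlo assertions
stable at the stated tolerances while keeping the whole suite fast on a
single core. Seeds derive from `numpy.random.SeedSequence` and stay below
2³¹. Tie-breaks: the trace peak is the first maximal bin (`argmax`);
derivative components are ordered by time after truncation to the two
largest by height.

## Known limitations

* Phenomenological release pulses — no mechanistic ODE model of
  Pmc1/Vcx1/organellar fluxes.
* Single cytosolic aequorin compartment; no pH/Mg²⁺ corrections.
* Between-replicate variability is purely photon statistics (see above).
* Primer efficiencies are inputs; no standard-curve estimation.
* No repeated-measures or nonparametric tests.
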