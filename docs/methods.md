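# Methods

## Model

The network is a discrete three-unit idealization of a tonotopically
organized competition stage assumed to sit downstream of primary auditory
cortex. Units at the A and B tone frequencies and at the midpoint carry
firing rate r, adaptation a, slow recurrent excitation e, synaptic
depression d (acting multiplicatively on the excitation) and an additive
Ornstein–Uhlenbeck noise χ that enters inside the firing-rate sigmoid, so
rates remain in (0, 1). Inhibition is treated as instantaneous
(proportional to the rates): every unit inhibits itself with strength
C_i(0) = β_i, the central unit exchanges inhibition with each peripheral
unit at tonotopic distance Δf/2, and the peripheral units inhibit each
other at distance Δf. In the local variant C_i decays as a Gaussian with
scale σ_i; in the global variant it is constant.

Parameters (defaults of the two presets):

| symbol | meaning | efix_ilcl | edyn_igbl |
| --- | --- | --- | --- |
| θ_F, k_F | sigmoid threshold, slope | 0.2, 12 | same |
| Λ₂, α₁, α₂ | input plateau fraction, rise times | 1/6, 15 ms, 82.5 ms | same |
| I_p, σ_p | input amplitude, tonotopic spread | 0.525, 8 st | 0.47, 8.5 st |
| g, γ | adaptation, noise strength | 0.065, 0.075 | same |
| β_i, σ_i | inhibition strength, footprint | 0.3, 10 st | 0.3, ∞ (global) |
| β_e, κ | excitation strength, depression | 0.7, 0 | 0.85, 0.25 |
| τ_r, τ_a, τ_e, τ_X, τ_d | timescales | 10 ms, 1.4 s, 70 ms, 100 ms, (–) | …, 3 s |

All times are seconds internally; Δf is in semitones; PR (tone onsets per
second) fixes the tone duration TD = 1/PR, so tones abut.

### Input construction

Each tone onset launches a double alpha-function impulse
(e²/α²) t² e^(−2t/α), the fast component normalized to unit peak at α₁ and
the slow plateau component to Λ₂ at α₂; impulses from successive tones sum
and are truncated below 10⁻⁸ (≈1 s after onset). Within each 4/PR triplet
cycle the A train has onsets at phases 0 and 2/PR, the B train at 1/PR,
and the fourth slot is silent. Drives are precomputed on the integration
grid and shared across noise realizations of the same stimulus.

**Input routing.** Every pathway is scaled by the spread function w, so a
unit's own tone arrives with amplitude w(0) = I_p, and the central unit
pools both trains at w(Δf/2). Peripheral units are driven by their
preferred tone only. This routing is a deliberate design decision and the
load-bearing one for the stimulus-parameter organization: if each
peripheral unit also received the opposite tone at gain w(Δf), the three
units' drives would become exchange-symmetric as Δf → 0 (the relative
cross gain is e^(−Δf/σ_p) ≈ 0.88 at 1 st), and by symmetry the central
unit could hold dominance for at most ~1/3 of the time at small Δf — no
regime of integrated predominance can exist. With own-tone-only peripheral
drive, the mechanism that selects the percept is temporal: the central
unit receives three evenly spaced pulses per triplet and bridges its
125 ms gaps on the excitation timescale τ_e, while each peripheral unit
must survive 250 ms gaps alone. Integration therefore dominates at small
Δf, where the central unit's pulse amplitude w(Δf/2) is near full, and
collapses at large Δf, giving the classical organization: integrated below
~4 st, segregated above ~8 st, bistable alternation in between, with the
ambiguous band contracting at higher presentation rates (shorter gaps are
easier for the peripheral units to bridge). The excluded cross term
remains available as `ModelParameters.peripheral_cross_gain` (a multiplier
on w(Δf), default 0) for exploration.

### Integration

Euler–Maruyama with fixed dt = 1 ms (a tenth of the fastest timescale
τ_r); the OU noise is updated exactly (decay e^(−dt/τ_X), innovation SD
γ√(1 − e^(−2dt/τ_X)), stationary SD γ). Initial conditions: r, a, e at 0,
d at 1, χ drawn from its stationary law — transients land in the excluded
first percept, so they do not contaminate statistics. A master seed spawns
independent per-trial substreams (numpy SeedSequence); a trial is a
deterministic function of (stimulus, parameters, dt, seed). Halving dt
changes the decoded mean dominance duration by well under 5 % (asserted in
the test suite). Non-finite states abort with a diagnostic naming the
time, seed and stimulus.

## Percept decoding

The three rate traces are smoothed with a centered 50 ms moving average
(window truncated at trace edges — those samples belong to the excluded
first/last durations anyway). The output is *integrated* where the
smoothed central rate exceeds the mean of the smoothed peripheral rates,
*segregated* otherwise; exact ties keep the previous sample's label. Label
runs shorter than one triplet cycle (4/PR) are absorbed into the ongoing
percept, shortest first: dominance shorter than one stimulus cycle is not
perceivable, and without this debounce the margin's occasional sub-triplet
flicker around a crossing splits durations that a human (or the
experimental 0.5 s minimum-duration rule) would never register. Within
segregated runs an optional secondary label marks whether A or B is in the
foreground; no statistic uses it. Duration extraction always drops the
final (incomplete) run, drops the first run (build-up) by default, and can
additionally drop durations below a configurable minimum (0 for model
output; 0.5 s mirrors the experimental key-press convention).

## Duration statistics

Durations are normalized by the mean of their percept type before pooling;
the coefficient of variation uses the sample SD (n−1). Gamma fits are
maximum-likelihood with location fixed at 0 (shape–scale convention, mean
kθ); log-normal fits use the closed-form MLE (μ, σ = mean and SD of
log-values). One-sample Kolmogorov–Smirnov tests compare the empirical
step CDF against the fitted CDF with the asymptotic p-value and treat the
fitted parameters as fixed — no correction for estimating them from the
same sample — replicating the customary procedure in this literature
rather than best practice; p-values near the threshold should be read
accordingly. Subsampling of large duration pools (e.g. to 1000) is seeded.

At the reference stimulus (Δf = 5 st, PR = 8 Hz, efix_ilcl, 50 × 240 s
trials) the pipeline yields ≈ 47 durations per trial with pooled mean
≈ 4.9 s and normalized CV ≈ 0.70. The pooled normalized distribution is
gamma-compatible and rejects the log-normal at n = 1000 — the reverse of
the shape commonly reported for this paradigm (log-normal but not gamma).
The difference survives dt halving and all cleaning conventions we tested;
it is an emergent property of the variant, documented rather than tuned
away.

## Sweeps

Proportion integrated U_int is total integrated time over total classified
time, pooled across trials without first/last exclusions (it is a time
budget, not a duration statistic); duration statistics apply the
exclusions. Equidominance is the linear interpolation of U_int through
0.5 across the bracketing grid pair. For the Levelt measure
η(S) = (T₁+T₂−2T_eq)/T_eq, T_eq is the normalized integrated branch
interpolated at the equidominance point; since both branches are convex
near the crossing, linear interpolation overestimates T_eq slightly and
biases η downward at the immediately adjacent grid points — η's sign there
is reliable only when equidominance falls on a grid point. The model's
global mean duration T_glob (used to normalize sweep branches, mirroring
the behavioral analysis) pools both percept types across the eight
experimental Δf conditions present in the sweep. Default trial counts: 12
per grid point, 50 per Δf-sweep point, both configurable; tests and the
figure-reproduction commands default to scaled-down counts (≥4 per grid
point, ≥10 per sweep point), with `--full` selecting paper-scale sizes.

In this implementation the efix_ilcl sweep at PR = 8 crosses equidominance
at Δf ≈ 5.5–5.9 st and the duration branches form the X diagram; η is
clearly positive from ~2 st on either side of the crossing (≈ +0.5 at
3 st, ≈ +0.2 at 9 st, rising outward) while within ±1.5 st the total
duration T₁+T₂ is flat and η hovers at 0 ± 0.05: the stronger percept's
branch moves more than the weaker's between adjacent conditions (majority
vote across the sweep), but the alternation-rate maximum sits slightly
above the U_int crossing. The edyn_igbl variant sits at equidominance
almost exactly at 5 st with shallower branches and a much smaller fraction
of the (PR, Δf) plane in single-percept dominance.

## Behavioral pipeline

The canonical duration table (CSV, or a MAT v5 mirror with one array per
column) has columns subject, repetition, delta_f, onset_s, duration_s,
percept, is_first, is_incomplete. Loading validates positivity, percept
labels and (optionally) the condition set; violations raise distinct
diagnostics. Exclusions: final incomplete and first durations always (for
subsequent-duration analyses), durations < 0.5 s (one triplet), and — as a
reproducible stand-in for by-inspection subject exclusion — subjects whose
grand mean duration T_glob exceeds the upper Tukey fence (Q3 + 1.5 IQR)
are flagged in the exclusion report and dropped only on request or by
explicit list. Every exclusion is itemized with its rule.

Each subject's durations are divided by their T_glob (grand mean across
both percepts, all repetitions, all conditions, post-exclusion), and each
subject contributes one mean integrated and one mean segregated score per
condition, so fast switchers do not dominate the group statistics; group
curves report mean ± SEM (SD/√N). Proportion integrated is computed per
trial as integrated time over classified time and averaged over
repetitions. For the per-subject Levelt measure, Δf = 5 st is treated as
the data's equidominance point and each subject's T_eq is the mean of
their integrated and segregated scores there (within a subject the two
agree only approximately, so their mean is the natural compromise).

Repeated-measures ANOVAs use the classical within-subject decomposition
(each effect tested against its subject-by-effect interaction error term),
computed via pingouin, with Mauchly's sphericity test and
Greenhouse–Geisser corrected p-values; complete cases only (incomplete
subjects raise, matching the convention of excluding subjects missing
conditions). The two-way analysis log-transforms the normalized durations
(natural log; the base cancels in F). Effects with exactly zero sum of
squares report F = 0, p = 1 rather than 0/0. The test suite cross-checks F
and the sums of squares against textbook formulas coded independently, and
the Greenhouse–Geisser ε against a constructed exactly-compound-symmetric
sample covariance.

## Synthetic cohorts

The generator emulates the experimental design (default 15 subjects × 3
repetitions × 8 Δf conditions of 240 s): subject grand means drawn
log-uniformly over 2.6–14.8 s (the span a cohort of fast-to-slow switchers
realistically covers); percept types alternating strictly within a trial
from a random first percept; per-duration log-normal draws with CV 0.83;
X-shaped mean structure (df/df₀)^∓b crossing at df₀ = 5 with b = 0.5, which
makes η = cosh(b ln(df/df₀)) − 1 ≥ 0, so generated cohorts satisfy the
generalized Levelt II property by construction; first durations inflated
by 1 + 1.5 e^(−(Δf−1)/5), largest at small Δf. The final duration is
truncated at the trial end and marked incomplete. It does not emulate
key-press mechanics (both/neither-key intervals, reaction lags),
within-session drift, or departures from strict alternation — so passing
pipeline tests demonstrate the analysis machinery, not the realism of any
particular cohort.

## Known limitations

- The pooled normalized duration distribution is gamma-like rather than
  log-normal-like (see above).
- η is indistinguishable from 0 within ±1.5 st of equidominance; the
  generalized Levelt II bias appears only at larger parameter offsets.
- The peripheral cross-input term is off by default (see Input routing);
  setting `peripheral_cross_gain = 1` restores the fully symmetric
  routing but abolishes integrated predominance at small Δf.
- Inhibition is instantaneous; no explicit inhibitory population, delays,
  attention, or continuous tonotopy.
- The MAT reader expects the documented column-array layout; arbitrary
  third-party MAT structures must be converted to the CSV dialect first.
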