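# Methods

Models, assumptions, parameter defaults and numerical choices. All tunables
live in `RunConfig` (`musclephys.io_core.CONFIG_DEFAULTS`) and are logged per
run; defaults quoted below are those values.

## 1. Torque traces

A `ForceTrace` is a uniformly sampled torque–time record (N·m, default
1 kHz) with subject metadata (genotype, age, bodyweight, lever arm, nerve
target) and a stimulus window. Validation enforces a uniform grid to 1 ppm,
consistency of `sampling_hz` with the time step, no missing samples, and a
stimulus window inside the record. Files are plain CSV with a `#`-prefixed
`key: value` header; `mN·m` and `ms` units are converted on read, and the
writer emits full-precision reprs so write→read round-trips are exact.

### Twitch model

Rise: amplitude-normalised exponential,
`y(t) = A·(1 − e^(−(t−t₀)/τ_r)) / (1 − e^(−s))` for `t₀ ≤ t ≤ t₀ + s·τ_r`,
so the noise-free peak equals `A` exactly at `t₀ + s·τ_r` (default span
`s = 5` rise constants, `τ_r = 12 ms`, `A = 2 N·m`). Decay: biexponential
`(1−w)e^(−Δ/τ_f) + w·e^(−Δ/τ_s)` with `τ_f = 50 ms`, `τ_s = 0.8 s`,
`w = 0.1`; the slow tail emulates the prolonged terminal relaxation of
dystrophic muscle. Additive white Gaussian noise, seeded.

### Tetanus model

During stimulation (default 1 s): saturating rise
`P·(1 − e^(−Δ/τ_r)) + d·Δ` with `τ_r = 50 ms`, plateau `P = 8 N·m` and
optional linear creep `d`. After stimulation: biexponential relaxation from
the end-of-stimulation value. The *end-of-stimulation* torque, not the peak,
is the tetanic reference throughout the package, because real plateaus
fluctuate and creep.

### ECD protocol model

Thirty eccentric contractions — three sets of ten, 4 s between contractions,
4 min between sets. Each contraction is a 0.7-s tetanus whose plateau is
scaled by

```
a_k = r_inf + (1 − r_inf)·exp(−(k − 1)/κ),   k = 1…30,
```

(`a₁ = 1`, monotone decay to `r_inf`; κ = 5 contractions by default, the
time scale over which most loss occurs in severely affected muscle). The
pedal rotation 0.5 s into stimulation is modelled as an additive
raised-cosine transient confined to the 0.2-s rotation window (height 0.6 ×
scaled plateau); because plateau torque is read *before* rotation onset, the
transient's exact shape is immaterial downstream — the pipeline only needs it
present to prove the reader is robust to it.

### Cohorts

Per-subject true final decrements are drawn from a normal truncated to
[0, 100] %. Truncation biases the mean of a naive `N(17, 11²)` upward by
~1.4 points, so by default the location is solved by bisection such that the
*truncated* mean equals the stated group mean (moment matching); the stated
summary statistic is then the true expectation of the generated cohort. The
decrement maps to the curve by `r_inf = 1 − decrement/100`.

## 2. Kinetics

- Baseline: mean over the 50 ms before stimulus onset (≥ 5 samples),
  subtracted and recorded.
- Contraction times: measured from stimulus onset to the first upward
  crossing of each decile of the reference (linear interpolation between
  samples), so the electromechanical delay is included. Twitch reference =
  peak (deciles 10–100 %, 100 % = time of peak); tetanus reference =
  end-of-stimulation torque (deciles 10–90 % plus 95 %).
- Relaxation times: from the reference point (twitch peak / end of
  stimulation) to the first downward crossing of `ref·(1 − x)`. Fractions the
  record never reaches are NaN and listed in `relaxation_unreached` — flagged,
  not fatal, because slow dystrophic relaxation frequently outlasts the
  recording window.
- Forces: absolute force = torque / lever arm (default 0.11 m); relative
  force = absolute / bodyweight.
- QC rules (reject, never raise): low SNR (peak < 5 × pre-stimulus noise sd),
  negative deflection (dip beyond 20 % of peak: antagonist co-stimulation),
  multi-peaked twitch (> 2 maxima above 50 % of peak with prominence ≥ 10 %
  of peak — prominence keeps sampling noise near the peak from counting), and
  tetanic plateau collapse (> 30 % drop below the running maximum during
  stimulation). Collapse applies to isometric tetani only; eccentric traces
  legitimately fall back after the lengthening transient and receive
  protocol-level QC instead.

## 3. ECD pipeline

Plateau torque = mean baseline-corrected torque over the 10 ms before
rotation onset (rotation onset from trace metadata when present, else
stimulus onset + 0.5 s). Protocol QC rejects individual contractions with no
measurable plateau, plateau below 5 × noise sd (dislodged electrode),
implausible sample-to-sample jumps (> 50 % of plateau) or a rise that has not
settled to 80 % of the plateau read; the protocol as a whole is rejected when
fewer than 80 % of contractions survive. Rejected contractions leave NaN gaps
at their protocol positions — indices never shift. The series is normalised
to the maximum *accepted plateau* (never a raw trace, so the eccentric spike
cannot inflate it): `N_k = 100·T_k/T_max`, final decrement `100 − N_final`,
flagged when the final protocol position was itself rejected.

`linear_fit` provides closed-form OLS with a two-sided t-test on the slope
(n − 2 df) for age–torque style regressions.

## 4. Synthetic sections

Geometry: up to `n_fibres` (default 200) Poisson-disc seed points
(dart-throwing, minimum spacing `0.65·√(area/n)`) inside a border margin of
`max_cell_radius + 12 px`; fibre interiors are the nearest-seed tessellation
cells clipped to a maximum radius of 80 px, with pixels closer than 3 px to a
cell boundary forming the collagen network. The margin must exceed the
maximum cell reach, otherwise peripheral fibres would touch the image border
and be (correctly) excluded by the particle filter, capping detection by
construction.

Intensity model (8-bit): positive channels per fibre drawn from
`N(180, 12²)`, negative from `N(20, 5²)` — background autofluorescence varies
less between fibres than specific staining, and the smaller negative sd keeps
the corrected outline channel clean inside fast-negative fibres (see below).
Collagen: 200 on boundaries, 2 inside fibres, plus `0.3 ×` the fast channel
(the bleed-through artefact the pipeline removes), plus `N(0, 3²)` background
noise everywhere. The in-fibre collagen base must stay below the fast-channel
background for integer subtraction to zero the interiors; a base of 5 with
negative-channel sd 12 left residual ≥ 1 levels inside fast-negative fibres,
shattering them into boundary webs.

Categories: seven (slow, fast, fast/slow hybrid, and four
regeneration-positive combinations), reported as five classes (type I,
type II, hybrid I/II, regenerating, unclassified). `reporting_composition`
splits a regenerating percentage over the four regeneration-positive
categories (0.6/0.25/0.1/0.05). Ground truth carries the instance label mask
and a per-fibre table. `corrupt_section` applies named corruptions (boundary
fusing, channel darkening, cropping) for robustness tests.

## 5. Fibre typing

1. Bleed-through correction: `clip(collagen − fast, 0, 255)` on integers,
   mirroring channel-arithmetic image subtraction.
2. Mask: boundary = corrected plane ≥ 1 (specks < 20 px discarded); fibre
   interiors are the inverse. Instances: marker-based watershed on the
   Gaussian-smoothed (σ = 3 px) interior distance transform, markers from
   `peak_local_max` (min distance 10 px) — this splits fibres whose shared
   outline is broken.
3. Particle filter: area ≥ 300 px, circularity `4πA/P²` in [0.40, 1.00]
   (clamped at 1.0 — digitisation can push a disc slightly past 1), and no
   contact with the image border. The perimeter is a Moore boundary-following
   chain code (cardinal steps 1, diagonal √2) on the hole-filled mask,
   matching particle-analysis conventions; the acceptance suite checks every
   keep/reject decision against an independently written brute-force tracer.
4. ROI means of the three myosin channels per instance.
5. Classification: per-channel positivity (mean > threshold) → 7-way
   category → reporting class. Thresholds are manual config values
   (default 100/100/100, the generator-agnostic midpoint) or automatic
   Otsu cuts on the 1-D ROI-mean distribution (needs ≥ 20 ROIs). A channel is
   flagged low-confidence when its two induced classes separate by < 4 pooled
   sds: an Otsu split of a *unimodal* normal separates by ~2.65 pooled sds, so
   any smaller cutoff could never flag a structureless channel.
6. Composition: per-image percentages over accepted ROIs; per-subject values
   are unweighted means over that subject's images (the subject, not the
   image or the pooled ROI set, is the unit of analysis); subjects with zero
   accepted ROIs are excluded with a warning.

`evaluate_detection` scores synthetic runs: an ROI matches the truth fibre
owning > 50 % of its pixels; detection = matched distinct fibres / all true
fibres; composition error = max absolute difference in reporting-class
percentages. Clean 1024² sections score detection ≥ 0.99 and composition
error < 0.5 points.

## 6. qPCR

Amplification efficiency is fixed at 2 per cycle. Replicates (≤ 3) collapse
to mean Cq, flagged when replicate sd > 0.5 cycles. Relative expression:
`log10 2^−(Cq_target − mean Cq_refs)` against HPRT1/RPL13A/SDHA (arithmetic
mean of Cq ≡ geometric mean of quantities). Isoform proportions:
`2^−Cq_i / Σ 2^−Cq_j` within the six-gene myosin panel (MYH7/2/1/4/3/8) or
the four non-regenerative genes; the minimum Cq is subtracted before
exponentiation (proportions are invariant to a common shift; this avoids
underflow at high Cq).

## 7. Statistics and power

- `welch_t`: two-tailed unpaired t with Welch df; both-groups-degenerate
  convention t = 0, p = 1.
- `holm_sidak`: step-down adjustment `1 − (1 − p₍ᵢ₎)^(m−i+1)`, made monotone
  by running maximum, returned in input order.
- Power: 2-group × T-timepoint repeated-measures design with compound
  symmetry (defaults T = 6, ρ = 0.7). The group main effect reduces to a
  two-sample comparison of subject means with variance
  `σ²(1 + (T−1)ρ)/T`; tested by noncentral F(1, 2n−2) with
  `λ = n·δ²/(2·var)`, effect `δ = f·(μ_WT − μ_affected)` (a trial shifting
  treated affected animals toward wild-type by fraction `f`), pooled
  `σ = √((sd_A² + sd_W²)/2)`. `sample_size` returns the least integer
  n ≥ 2 reaching the target power (default 0.8 at α = 0.05);
  `simulate_power` cross-checks by Monte-Carlo (the pooled-variance t is the
  square root of the F statistic). With the ECD group statistics
  (76 ± 14 vs 17 ± 11) and f = 0.25 this model returns n = 10 per group;
  it is deliberately a documented, reproducible covariance model rather than
  a parity attempt with any specific power-analysis GUI, which can return
  smaller n under other covariance/test configurations.

## 8. Reproducibility and problem sizes

Every generator is a pure function of (params, seed); cohort and image-cohort
helpers derive per-item seeds from one master seed. `run_study` writes
sorted-key run logs so reruns are byte-identical. Desk-scale problem sizes
were chosen so the full test suite runs in ~1.5 min and the acceptance script
in ~1.5 min on one CPU: ECD cohorts of 53/30 protocols (30 × ~1.55 s traces
at 1 kHz) and image cohorts of 4–5 subjects × 5 images at 1024² with ~200
fibres each — large enough that sampling tolerances (2·sd/√n; 2 percentage
points for compositions) are meaningful, small enough to iterate quickly.
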