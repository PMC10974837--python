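# Methods

## The measurement problem

A dual-heat-flux (DHF) probe estimates core body temperature (CBT)
non-invasively by pressing two adjacent measurement channels against the
skin. Each channel is a slab of thermally resistive material
instrumented with temperature sensors on both faces (the "TT" sensor
family) or with a heat-flux sensor plus a skin-side temperature sensor
(the "HT" family). A single channel would need the skin's
heat-transfer coefficient h_t — unknown and highly variable across
people and body sites — to extrapolate from the skin surface to the
core. Two channels with *different* thermal resistances carry different
fluxes, and eliminating h_t between the two channel balance equations

    CBT = T_ss1 + q_1/h_t ,   CBT = T_ss2 + q_2/h_t

yields CBT estimates that depend only on measured quantities (plus, for
the TT family, the probe's characteristic parameter k = h_s2/h_s1).
This package simulates such probes, applies the six estimator variants,
and quantifies how sensor noise propagates into the CBT estimate.

## Forward model

The stack blood–skin–channel–air is modelled as a one-dimensional
steady-state series resistance chain. Each layer is summarised by a
heat-transfer coefficient h = k/d (W/(m²·K)); channel i has overall
coefficient 1/h_i = 1/h_t + 1/h_si + 1/h_sa and carries flux
q_i = h_i·(CBT − T_amb). Surface temperatures follow by walking down
the chain: T_ssi = CBT − q_i/h_t, T_sai = T_ssi − q_i/h_si.

Assumptions: laterally infinite layers (no edge leakage), constant blood
temperature, steady state (the governing equations are algebraic; no
thermal capacitance), and a single convective film coefficient h_sa
applied identically to both channels. All readings are affine in the
driving gradient CBT − T_amb, so temperatures are handled in °C
throughout without loss.

Default parameters (units, value, rationale):

| parameter | unit | default | meaning |
|---|---|---|---|
| k_s1, k_s2 | W/(m·K) | 0.15 | channel material conductivity (PDMS) |
| d_s1, d_s2 | mm | 15, 30 | channel thicknesses → h_s1 = 10, h_s2 = 5 W/(m²·K), ratio 2 |
| k_t | W/(m·K) | 0.37 | skin conductivity |
| d_t | mm | 2.5 | skin thickness → h_t = 148 W/(m²·K) |
| h_sa | W/(m²·K) | 6.1 | natural convection, ~3 cm plate |
| CBT, T_amb | °C | 37, 25 | default operating point |

## Estimator variants

Six variants are implemented. `HT` uses absolute skin temperatures and
fluxes; `TT` uses four absolute temperatures plus k. The "p" variants
replace inter-sensor differences by *paired* differential measurements
(a bias-calibrated sensor pair, e.g. matched in an oil bath, whose
differential uncertainty u_ΔT is two orders of magnitude below the
absolute u_T). The "pm" variants additionally average the
algebraically equivalent re-expressions of the estimate anchored on
each available absolute sensor: two equations for HTpm, four for TTpm.
On error-free readings every variant recovers CBT exactly, for any
probe with h_s1 ≠ h_s2 and any T_amb ≠ CBT; this exactness is asserted
to 1e−9 °C over an operating grid in the test suite.

All variants share a singular denominator — q_2 − q_1 (HT family) or
k·ΔT_s2 − ΔT_s1 (TT family) — which vanishes when T_amb = CBT or when
the channels are identical. A vanishing denominator yields a
non-finite, flagged estimate rather than an exception, and non-finite
Monte Carlo draws propagate into the trial statistics and are counted,
never dropped: the blow-up magnitudes near the singular point are part
of what the toolkit is for. Denominators are compared to exact zero
only (no epsilon clipping), so near-singular amplification is
preserved.

## Noise model

Each measured quantity receives an independent zero-mean Gaussian
error: u_T = 0.053 °C (absolute temperature; precision analog sensor
datasheet accuracy), u_ΔT = 0.0006 °C (paired differential; twice the
intrinsic output noise of one sensor), u_q = 1.3 W/m² (thin-film flux
sensor plus ADC), u_h = 0.12 W/(m²·K) (channel coefficient, from 0.1 mm
thickness and 1% conductivity tolerances). The per-variant mapping of
draws encodes which readings are physically independent: averaging
variants share their differential/flux/k draws across the averaged
equations while each absolute base temperature gets a fresh draw — this
sharing is exactly what lets averaging reduce variance. Design choices
that were genuinely open, with the adopted resolution:

- **k as a measured quantity.** For TT-family variants, k is formed as
  the ratio of separately perturbed h_s1, h_s2 (SD u_h each), so the two
  coefficients appear as distinct uncertainty components. A
  `h_noise_for_tt: false` switch restores the strict reading in which
  TT-family variants carry temperature noise only.
- **HTpm flux sharing.** Whether HTpm's two averaged equations see the
  same flux draw is not dictated by the estimator algebra; the default
  shares the draw (one physical measurement event), and
  `share_flux_in_htpm: false` draws independently.
- **Paired differentials are drawn fresh**, not derived from two noisy
  absolute readings — pairing calibrates the bias out, so the
  differential's error is its own small noise, independent of the
  absolute channel.
- **`ut_interpretation: uniform_bound`** optionally treats the four
  values as half-widths of uniform error bounds (effective SD value/√3)
  instead of Gaussian SDs; the default is Gaussian.

Not modelled: temporally correlated noise, drift, quantization, lateral
heat leakage, perfusion/thermoregulation. Passing tests therefore speak
to the propagation arithmetic under idealized sensor noise, not to
in-vivo accuracy.

## Monte Carlo procedure

One trial: simulate the error-free readings, draw `n_reps` noisy
measured sets, apply the estimator, and take the sample SD (n−1
denominator) of the estimation errors. `n_trials` independent trials
give `mu_cbt` (mean of trial SDs — the uncertainty prediction) and
`su_cbt` (SD of trial SDs — the repeatability of that prediction).
Defaults are 10,000 reps × 100 trials; the CLI's `--fast` mode uses
2,000 × 20. Per-trial streams are spawned deterministically from the
master seed (`numpy` `SeedSequence.spawn`), so runs are bit-for-bit
reproducible and trials independent; sweep cells get their own
substreams so adding variants or grid points does not perturb others.

Sweep experiments (one parameter varied, all else default): ambient
−15…45 °C in 0.5 °C steps plus a narrow 36.95…37.05 °C sweep in 1 m°C
steps for the paired TT variants (`e1`, `e1n`); CBT 35…45 °C in 0.25 °C
steps (`e2`); channel conductivity 0.01…100 W/(m·K) over 60 log-spaced
points at fixed ratio 2 (`e3`); coefficient ratio 1.25…10,000 over 60
log-spaced points by thickening channel 2 (`e4`); h_sa 6…104 W/(m²·K)
in steps of 2 (`e5`). Grid resolutions are the package's own choice,
set to resolve the reported features at desk scale.

## First-order budget

At a stable operating point the combined uncertainty is
u_c² = Σ (∂CBT_e/∂x)²·u_x² over the variant's independent components,
and ru(x) = (c_x·u_x)²/u_c² is each component's share. Sensitivities
are hand-derived closed forms; an independent central-finite-difference
oracle (step 1e−6 of a per-component characteristic scale) is asserted
against them to 1e−6 relative in the test suite. h_s1/h_s2 enter the
TT family only through k and are propagated by the chain rule
(∂k/∂h_s1 = −k/h_s1, ∂k/∂h_s2 = 1/h_s1), which fixes the structural
share ratio ru(h_s2)/ru(h_s1) = (h_s1/h_s2)² = 4 at the default probe;
similarly HT's skin-sensor share ratio is (q_1/(q_2−q_1+q_1))²-driven,
numerically 1.875 at the defaults.

Two structural facts worth noting, both asserted in tests:

- **Gradient invariance.** Because every reading is affine in
  CBT − T_amb, the temperature-component sensitivities are *invariant*
  to ambient temperature, and the h-component sensitivities scale
  linearly with the gradient. Sensitivities blow up as the channel
  ratio approaches 1 — not as T_amb approaches CBT at a fixed probe.
  The near-CBT instability seen in Monte Carlo is a breakdown of the
  linearization (noise pushing the denominator through zero), not a
  growth of the partials.
- **Second-order inflation for flux variants.** At the defaults the
  flux noise is ~15% of |q_2 − q_1| (σ = 1.3·√2 on 11.96 W/m²). The
  resulting ratio-of-normals nonlinearity inflates the true (MC)
  uncertainty above the first-order value by a roughly constant factor:
  measured at 2×10⁶ reps, +4.1% (HT), +4.3% (HTp), +6.1% (HTpm),
  +2.4% (TT), +0.3% (TTp), +0.9% (TTpm). Since su_cbt shrinks as
  1/√n_reps while this gap is constant, a "within 3·su_cbt" comparison
  between MC and Taylor holds only for the effectively linear paired TT
  variants; the suite asserts 10% relative agreement for the others and
  documents one strict-band check that is expected to fail for
  HTp/HTpm for exactly this reason.

## Instability near T_amb = CBT

All variants become unusable near T_amb = CBT, but *where* the Monte
Carlo uncertainty peaks differs by variant. For unpaired variants the
singular term's numerator carries u_T-scale noise, so mu_cbt explodes
at the singular point itself. For paired variants the numerator
carries only u_ΔT-scale noise, so exactly at T_amb ≈ CBT their mu_cbt
collapses back toward u_T; their blow-up peaks millidegrees (TTp/TTpm)
or degrees (HTp/HTpm, where the flux denominator becomes
noise-dominated around g ≈ 1–2 °C) away from the singular point.
Instability is therefore checked as the maximum over a variant-specific
ambient window (the wide 33…37 °C grid for the flux/unpaired variants,
the narrow millidegree sweep for TTp/TTpm) exceeding the stable-region
value by more than an order of magnitude. In the singular window the
error distribution is Cauchy-like: mu_cbt has no finite expectation,
individual sweep points scatter over orders of magnitude, and the
window maximum is the robust summary.

## Published share table

The per-component share percentages published for this probe class are
not reproducible from the datasheet-derived default SDs: back-solving
the printed HT/HTp rows implies an effective u_q ≈ 2.39 W/m² and the
printed TT row an effective u_h ≈ 0.220 W/(m²·K), and the scaling
behind the TTp row is not recoverable at all. The budget is therefore
validated structurally — normalization to 1 within 1e−12, the
closed-form share ratios 1.875 and 4.0, temperature-share dominance
(>80%) — rather than against the printed percentages.
`taylor.compat_share_noise()` exposes the back-solved effective values
for side-by-side comparison only.

## Numerical choices and limitations

- Sample SDs use the n−1 denominator everywhere; mu/su are plain mean
  and sample SD over trials.
- A perturbed h_s1 ≤ 0 (5σ+ event at realistic settings) is redrawn and
  logged; perturbed h_s2 may go negative (it does, by design, at
  extreme channel ratios — driving the right-hand rise of the ratio
  sweep's U-shape).
- Estimator kernels are vectorized over numpy arrays; the scalar API
  wraps the n = 1 case of the same kernels, so both paths share one
  implementation.
- The model is steady-state only; transient response, 2-D/3-D effects,
  and empirical validation are out of scope.
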