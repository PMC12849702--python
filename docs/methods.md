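# Methods

This note documents the models and procedures implemented in `fernspike`,
the defaults chosen where the underlying science leaves the design open,
and what the package's synthetic tests do and do not demonstrate.

## Assemblage quantification

Relative abundances are percentages of the **terrestrial pollen + spore
sum**: marine palynomorphs (dinocysts) and the exotic marker are excluded
from numerator and denominator. Reworked palynomorphs are not treated
specially — if a taxon is mapped to a terrestrial group it counts. Group
membership is configuration (`TaxonGroupMap`), not code; the fern group
carries a Gleicheniaceae sub-flag so fire-adapted ground ferns can be
reported separately.

Absolute concentrations use exotic-spike normalisation,
`c = n · N_spike / (n_Lyc · w)` in grains per gram of dry sediment. A slide
with zero counted marker grains has no defined concentration; this raises
an explicit error rather than propagating NaN, always with the sample
depth in the message. Fold changes are ratios of interval *mean*
concentrations with tephra-flagged samples excluded by default (a flag
re-includes them). Nothing is rounded internally; CSV export rounds to 4
significant digits.

## Chronology

Depths are metres below sea floor (mbsf), positive downward; the aligned
coordinate is h = base − depth, positive upsection, with the CIE base at
h = 0. Annual diatom laminae convert to sedimentation rates as
`cm/ky = µm/yr ÷ 10`. Two lamina readings are carried as an enum — one
bloom + mixed layer per year (200 µm/yr → 20 cm/ky) or two of each
(400 µm/yr → 40 cm/ky) — and duration estimates propagate both ends as a
range. Instantaneously deposited beds (tephra) are subtracted from
interval thicknesses before converting to time.

CIE-base detection: the baseline is the mean δ¹³C of a pre-event window
(default: the deepest 30 % of the series, minimum 3 samples); scanning
upsection, the first sample more than a threshold below the baseline is
the base. The default threshold is **1.0 ‰**: comfortably above analytical
and bulk-organic-matter mixing noise (~0.1–0.3 ‰), comfortably below the
3–4 ‰ excursion. On tied first crossings the deeper (older) sample wins —
the conservative, earliest-base choice, which falls out of the scan order.

## Synthetic records

The generator emulates an expanded, annually laminated marine-margin
record of the event: a conifer-dominated pre-event assemblage
(~2×10⁵ grains/g total, fern spores <10³ g⁻¹), an abrupt fern spike
immediately above the CIE base (fern 40 % relative, 5.6×10⁴ g⁻¹ — 70-fold
above pre-event — with conifers collapsing below 200 g⁻¹ and microcharcoal
at 2.6 % of the palynofacies), an angiosperm-dominated interval above, a
3.5 ‰ δ¹³C excursion with a step at the base and a 60-cm onset ramp,
mm–cm tephra beds, and a 20 cm/ky default sedimentation rate with 4-cm
sampling. Multi-site sets hold event *durations* fixed so interval
thicknesses scale with each site's rate.

Counting statistics follow the standard model for palynological counts:
the terrestrial total is Poisson (default expectation 300 grains), group
composition is multinomial on depth-dependent fractions, and the counted
marker grains are Poisson with mean set by the latent concentration ratio,
so spike normalisation recovers the latent grains/g in expectation. δ¹³C
noise is Gaussian (default sd 0.15 ‰). Phase transitions are hard steps —
the abruptness is the phenomenon. The δ¹³C profile places an initial
1.2 ‰ drop *at* the base sample because the base is defined as the first
anomalously low data point. A noise-free mode replaces draws with
error-diffusion rounding across samples, so interval means stay unbiased
even where a group's expected count per slide is a fraction of a grain.

What passing recovery tests show: the estimators are unbiased and the
detection/alignment logic is correct under the assumed noise model. What
they do not show: robustness to taphonomic overprinting, reworking,
bioturbated or hiatus-bearing sections, or taxonomically mis-assigned
counts — none of which the generator simulates.

## Carbon-cycle box model

### Structure

Five reservoirs (PgC, δ¹³C): atmosphere (2,120; −6.5 ‰), surface ocean
(900; +2.5 ‰), deep ocean (38,000; +2.5 ‰), plant (1,000; −25.5 ‰), soil
(1,800; −25.5 ‰). Fluxes: injection → atmosphere; NPP (atmosphere → plant,
ε_land = −19 ‰); litter (plant → soil, τ_P = 33.3 y); soil respiration
(soil → atmosphere, τ_L = 60 y, optionally ×Q10^(ΔT/10)); gross air–sea
exchange k_g·pCO₂ with k_g = 0.06 PgC yr⁻¹ ppm⁻¹ (60 PgC/yr at baseline);
surface–deep overturning, 38 PgC/yr each way (τ_mix = 1,000 y); kerogen
oxidation → atmosphere (F_ker0 = 0.06 PgC/yr at −25 ‰); a
silicate-weathering sink F_w0·(pCO₂/pCO₂,0)^0.3 with F_w0 = F_ker0.
Surface-ocean pCO₂ follows a Revelle power law pCO₂,0·(M_S/M_S0)^10 —
the simplest closure that lets rapid ocean uptake drive the post-spike
pCO₂ decline. Temperature is ΔT = 5 °C · log₂(pCO₂/pCO₂,0).

¹³C is carried as normalised isotope mass m·(1 + δ/1000); every flux
carries its source's δ plus any fractionation, so carbon and ¹³C budgets
close to round-off (verified to <10⁻⁶ relative over full runs).

### Steady state and isotopic closure

The pre-event state is an exact equilibrium: plant = NPP·τ_P, soil =
litter·τ_L, air–sea and overturning gross fluxes balanced, silicate sink =
kerogen baseline. Two closures make the *isotopic* state exactly steady as
well: (i) air→sea transfer carries δ_atm + 9 ‰ (an equilibrium
fractionation placing the ocean ~9 ‰ above the atmosphere, as observed);
(ii) the silicate/burial sink removes carbon at the kerogen composition
(−25 ‰), so the exogenic input–output loop is isotopically closed. With
no biological pump in the flux set, deep and surface share one δ¹³C.

### Forcing and feedbacks

The injection is 0.98 PgC/yr for 5 ky (4,900 PgC) — a volcanic/thermogenic
source at the upper end of the 1–5 ky onset-duration estimates. Its δ¹³C
is **calibrated**, not assumed: a bracketed root-find on [−60, −22] ‰
drives the control run's surface-ocean CIE to 3.5 ± 0.05 ‰ (the calibration
is monotone: more depleted carbon, deeper excursion). The GPP multiplier
drops instantaneously to 1 − r at t = 0 (r = 0.3/0.5/0.7 in the scenario
suite) and recovers linearly at 0.3 % of pre-event GPP per millennium
(interpreted as percent of *pre-event* GPP, not of the remaining deficit;
an exponential-recovery option exists but is not the default).

The kerogen feedback is linear in the biosphere deficit,
F_ker0·(1 + γ·d). The gain defaults to **γ = 1.2**, derived from the
stabilization balance rather than fitted: requiring the excess kerogen
source to cross the opposing sinks (silicate excess ≈ 0.014 PgC/yr at a
body-phase pCO₂ of ~2× baseline, plus biosphere regrowth uptake
2,800 × 0.003/ky ≈ 0.008 PgC/yr) at a deficit of d* = 0.3 gives
γ = (0.014 + 0.008)/(0.06 × 0.3) ≈ 1.2. A Q10 multiplier on the kerogen
flux is implemented but off by default: with the sink exponent 0.3 and
5 °C per doubling, a temperature-multiplied source scales as pCO₂^0.5 and
outruns the sink, leaving no post-event equilibrium (runs never stop
warming). The deficit term alone preserves the intended mechanism — the
weathering response to destabilised, vegetation-poor landscapes — with a
stable long-term balance.

The respiration Q10 feedback is likewise implemented but disabled in the
headline scenarios: with donor-controlled soil (τ_L = 60 y), a persistent
Q10 rate increase shifts the soil equilibrium to input·τ_L/q and drags the
50 %-GPP stock minimum to ~60 % loss, whereas the scenario definitions
intend the stock trajectories to track the imposed GPP multiplier
(minimum ≈ the imposed reduction).

### Numerics

Explicit Euler at **dt = 0.25 y** over −20 to +250 ky, state stored every
10 y. The step size is set by stability, not accuracy: the air–sea
exchange Jacobian is ≈ 0.67·(M_S/M_S0)⁹ yr⁻¹ and exceeds the Euler
stability bound for dt = 1 y once the surface ocean holds ~10 % excess
carbon, which every feedback scenario reaches. dt = 0.25 y is stable with
margin; halving it changes peak pCO₂ by far less than 0.5 % (tested). A
250-ky run costs ~10⁶ steps, a few seconds on one CPU. Reservoir masses
are guarded (> 0) with the offending reservoir and time reported on
violation. "Time pCO₂ stops rising" is measured on a 1-ky boxcar-smoothed
series as the last time the derivative is positive — i.e. the moment after
which pCO₂ only declines. (A "first stall after injection end" variant is
provided, but it triggers during the post-spike ocean-uptake dip, which is
carbon repartitioning, not feedback exhaustion.) Control-relative
diagnostics use a body-phase window of 20–120 ky after onset
(configurable).

## Known limitations

* **No carbonate-sediment compensation.** The ocean's long-term buffering
  here is DIC-only, so ~50 % of marginal carbon stays airborne at
  equilibrium. Onset-peak amplifications are therefore faithful, but
  multi-10-ky quantities — the body-phase ΔpCO₂ plateau, the duration of
  the kerogen-sustained rise, and the body-phase δ¹³C suppression — come
  out larger/shorter than they would with seafloor CaCO₃ dissolution
  buffering the same perturbation. This is the dominant structural
  uncertainty in the scenario diagnostics.
* The terrestrial release is fast (plant and soil turnover of decades),
  producing a sharp early δ¹³C transient in the surface ocean; slower or
  staged biomass loss would smear it.
* One well-mixed surface box: no latitudinal or thermocline structure, no
  marine productivity response, no methane-specific chemistry, no orbital
  forcing.
* The scenario GPP collapse is imposed, not emergent (no CO₂ fertilisation
  by default, no climate–vegetation coupling); the model tests the carbon
  consequences of the reconstructed disturbance, not its causes.
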