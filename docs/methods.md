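# Methods

## Scope and data model

The package analyses three kinds of records: A–Ci response curves
(`ACiCurve`: ≥ 5 strictly increasing Ci points at one irradiance),
synchronized gas-exchange traces (`GasExchangeTrace`: 10-s records of
PPFD, A, gs, Ci, Ca, leaf temperature, optionally chamber fluorescence),
and PAM-fluorometer logs (3-min records of PPFD, Fs, Fm′). All traces
are time-ordered; integration and time-averaging use the trapezoidal
rule over actual timestamps, so irregular sampling and gaps are handled
without resampling. A rectangular (left-Riemann) alternative is exposed
because at 10-s sampling of smooth traces the two differ by well under
0.1% and some instrument workflows report running sums.

## Steady-state FvCB model

Net assimilation is the minimum of the Rubisco-limited and
RuBP-regeneration-limited rates. The kinetic constants (Kc, Ko, Γ\*, Rd)
default to rice-leaf values at 30 °C and are held fixed — no
temperature-response functions are applied, since all supported
protocols run at a controlled leaf temperature near 30 °C. Kc and Ko are
interpreted as mole fractions (µmol mol⁻¹, mmol mol⁻¹): these are the
only units under which Michaelis constants of this magnitude are
dimensionally coherent, and per-area unit strings sometimes attached to
such values in the literature are treated as typographical. Rd is a
fixed constant, not a fitted parameter. Triose-phosphate-utilisation
limitation is not modelled.

The light response of electron transport is a non-rectangular hyperbola
with curvature θ = 0.7 and initial quantum yield α = 0.3 mol e⁻ (mol
photons)⁻¹ by default, both configurable. At the saturating measurement
irradiance of A–Ci protocols (1500 µmol photons m⁻² s⁻¹) J sits within
~10% of Jmax and the fitted Jmax is insensitive to these defaults; they
matter only when simulating sub-saturating light.

## A–Ci fitting

`fit_aci` is a segmented least-squares fit made deterministic by an
explicit assignment loop: each point is assigned to the branch that is
minimal under the current parameters, each branch capacity is refit to
its own points (Vcmax on the Rubisco side, Jmax — through J at the
measurement irradiance — on the RuBP side), and the loop repeats until
the assignment stabilises (at most 20 rounds; an assignment revisited is
accepted as converged, since a boundary point can oscillate without
moving the solution). Vcmax is initialised by inverting the
Rubisco-limited equation at the three lowest-Ci points and Jmax at
1.5·Vcmax. A final joint least-squares polish on the minimum-rule model
removes the small bias of hard assignment. Fewer than three points on
either branch raises a degenerate-fit error naming the branch — a curve
truncated below the transition simply carries no information about Jmax.
Points are unweighted and the transition region is not excluded; both
choices are surfaced rather than hidden because instrument protocols
differ here.

## Induction analysis

A(t) and gs(t) after a step increase in irradiance are fitted with a
logistic, v(t) = v_i + (v_f − v_i)/(1 + exp(−(t − t50)/s)), with v_i
fixed to the pre-step mean so the fit spends its three free parameters
on the rise. Induction times follow in closed form,
t_f = t50 + s·ln(f/(1−f)). A flat trace (rise below 0.1% of scale) is
flagged degenerate rather than fitted. Cumulative CO₂ fixation (CCF_T,
default horizon 600 s) integrates the *measured* A, not the fitted
curve, and retains negative transients.

Limitation partitioning rescales observed A to the final steady-state
Ci assuming Rubisco-limited kinetics:
A\*(t) = A(t)·[(Ci_f − Γ\*)/(Ci_f + Km)] / [(Ci(t) − Γ\*)/(Ci(t) + Km)].
The diffusional limitation DL = (A\* − A)/A_f is the share of the
steady rate lost to low intercellular CO₂, the biochemical limitation
BL = (A_f − A\*)/A_f the remainder, and BL + DL = 1 − A/A_f holds by
construction at every record. The Rubisco-limited assumption is the
standard choice for a high-light step at sub-saturating Ci; its known
artefact — mildly negative BL at elevated CO₂, where the true operating
point is RuBP-limited — is bounded in practice (|BL| excursions < 0.05
in the shipped scenarios) and excursions outside [−0.1, 1.1] are
flagged. Steady-state end values A_f and Ci_f are means over the final
120 s (configurable). Records with Ci ≤ Γ\* are skipped with a flag.
Mean iWUE is the time-weighted mean of instantaneous A/gs (mean of
ratios, matching per-record plotting, not ratio of means).

## Fluorescence

ΦPSII = (Fm′ − Fs)/Fm′ and ETR = 0.5 × 0.84 × ΦPSII × PPFD; the
PSII fraction and absorptance are configurable but never estimated.
Records with Fs > Fm′ (failed saturating pulses) have ΦPSII clamped to
zero with a per-record flag so integration stays usable; NPQ =
(Fm − Fm′)/Fm′ is left unclamped when negative, flagged instead,
because a drifting Fm baseline is a diagnosis the analyst should see.
Fm for NPQ comes from the dark-adapted pre-dawn pulse (trace-level
metadata, overridable). Integrated ETR uses the trapezoid over actual
timestamps; gaps > 3× the nominal interval warn but do not interrupt.
ETR–PPFD binning uses left-open right-closed bins with configurable
edges; empty bins are omitted and listed.

## Dynamic-leaf simulator

The simulator is the package's ground-truth source, emulating the
chamber instrument: step protocols (20 min at 50 then 30 min at 1500
µmol photons m⁻² s⁻¹, 10-s sampling, at 400 or 800 ppm), a 12-h
fluctuating day (half-sine envelope, default peak 1200 µmol photons
m⁻² s⁻¹ — a clear summer day — times a two-state sun/shade telegraph
process with log-uniform dwell times of 10–300 s and a configurable
shade depth), and 3-min field PAM schedules.

Per time step: gs relaxes first-order toward a target linear in PPFD
between gs_min (0.05) and gs_max (0.45 mol m⁻² s⁻¹) saturating at
1000 µmol photons m⁻² s⁻¹, with separate opening (300 s) and closing
(120 s) time constants; a scalar Rubisco-activation state multiplying
Vcmax relaxes (τ = 240 s) toward a target that is 1 at or above the
50-µmol background level of the step protocols and falls linearly to a
dark-resting 0.3 — so by default any working light keeps the target
fully activated and the induction transient is stomatal, while raising
`act_ppfd_sat` gives the biochemical state its own lag. Because light is
piecewise constant within a step, the exponential relaxation updates are
exact, which is why integrated outputs are invariant to step halving to
within the integration rule's own error (< 0.5%).

Ci at each step solves the supply–demand balance
A(Ci) = (gs/1.6)(Ca − Ci) by bisection to |ΔCi| < 0.005 µmol mol⁻¹ on
(0, Ca + 1.6(Rd + 5)/gs]; the bracket always straddles the root because
demand is below supply at Ci → 0 and above it at the upper end. In
darkness the root sits above Ca (Ci = Ca + 1.6·Rd/gs) with A = −Rd.
Boundary-layer conductance is infinite by default (chamber-fan regime);
a finite value combines in series. Chamber fluorescence is synthesised
so that ETR recomputed from (Fs, Fm′, PPFD) equals 4(A + Rd) capped at
J(PPFD) — gross assimilation times four electrons, with no separate
photorespiratory electron stream — keeping gas exchange and fluorescence
mutually consistent for round-trip tests. Field PAM traces instead use
an explicit efficiency model ΦPSII = φ₀/(1 + PPFD/K) (φ₀ = 0.78,
K = 450), giving the saturating, monotone ETR light response typical of
field leaves. NPQ is not synthesised; NPQ analysis is exercised on
hand-built records, since inventing a quenching model would add an
unconstrained moving part.

Noise is applied last: additive Gaussian on A (default sd 0.3 µmol m⁻²
s⁻¹, the scatter of a well-sealed chamber at 10-s averaging),
multiplicative on gs (cv 2%), additive on fluorescence signals (sd 5
instrument units). All draws flow from one generator seeded explicitly;
identical seeds give bit-identical traces.

### What the simulator does and does not emulate

It reproduces the *structure* of the measurements — sampling cadences,
induction shapes, fluctuating-light statistics, supply–demand coupling,
noise magnitudes — so parameter-recovery and ordering tests are
meaningful. It does not emulate leaf energy balance or transpiration
dynamics (chamber temperature is held fixed), mesophyll-conductance
transients, photoinhibition over days, or the exact recorded field
light sequence (the diurnal generator matches its statistical character,
not the sequence itself). Passing tests therefore demonstrate that the
analysis chain is correct and well-conditioned on data of this
structure, not that any particular leaf obeys the simulator's kinetics.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use 12-point A–Ci curves
(200 noisy replicates), 100 noisy induction replicates, 1000 random
draws against a 10⁵-point grid oracle for the Ci solver, 30-min step
traces at 10-s sampling and 12-h days at 10–60-s sampling — sizes
matching the corresponding laboratory protocols while keeping the whole
suite in the minutes range. Ties in the minimum rule are resolved toward
the Rubisco branch; bin edges are right-closed; percent differences are
100·(other − reference)/reference, so the two directions multiply to
unity rather than summing to zero.

## Known limitations

- The Jmax estimate is conditional on the assumed J(PPFD) form; at
  saturating measurement light the sensitivity is ~1% but curves
  measured at lower irradiance would need θ and α fixed from data.
- Limitation partitioning inherits the Rubisco-limited assumption and
  slightly misstates BL at elevated CO₂ (see above).
- The gs target model has no humidity or CO₂ response; simulated gs
  differences between CO₂ treatments are absent by construction, so
  iWUE contrasts across CO₂ come from A alone.
- Group summaries expose mean ± SE and n only; inferential statistics
  (ANOVA, multiple comparisons) are left to dedicated packages.
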