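# Methods

`trichodiel` simulates the diel physiology of a single *Trichodesmium*
trichome, treated as one cylindrical, well-mixed compartment.  The state
comprises per-biomass stores (carbohydrate CH₂O, carbon skeletons CS, fixed
nitrogen N), intracellular O₂, six Fe pools (photosystems, active and
inactive nitrogenase, buffer, storage, maintenance), and log biomass.  All
internal computation uses seconds, mol per mol biomass C, mol O₂ m⁻³, and
µmol Fe (mol C)⁻¹; growth rates are reported in d⁻¹.

## Membrane O₂ permeability and physical exchange

The membrane's relative O₂ diffusivity ε (relative to seawater) is either
fixed (ε = 1.0×10⁻⁴, the observationally constrained reference) or
dynamically regulated by intracellular O₂,

    ε(O₂) = ε_max · O₂ / (O₂ + k_O2_diff),

with ε_max = 2.0×10⁻⁴ and k_O2_diff = 0.213 mol m⁻³ (air saturation at
25 °C, 34 PSU), so that at air-saturated intracellular O₂ the dynamic
membrane coincides with the fixed reference.  High intracellular O₂ opens
the membrane (venting photosynthetic O₂), low O₂ closes it (shielding
nitrogenase from influx).  The response is instantaneous; a first-order lag
hook exists for sensitivity work.

Physical exchange uses the series-resistance solution for a cylinder of
cytoplasm radius R wrapped by a membrane of thickness Lg and a diffusive
boundary layer Lb:

    T_O2 = 2π·d_O2·(L/V) / [ ln((R+Lg)/R)/ε + ln((R+Lg+Lb)/(R+Lg)) ] · (O₂_ext − O₂).

Geometry defaults (R = 7 µm, Lg = 0.6 µm, Lb = 20 µm, L = 1 mm,
V = cylinder volume) describe a wide trichome whose multi-layer cell
envelope acts as the effective diffusion barrier; they are uncalibrated
defaults, chosen so that the O₂ exchange conductance per biomass carbon
(with cytoplasm carbon density ρ_C = 1250 mol C m⁻³) is commensurate with
the cell's metabolic O₂ fluxes — a leakier membrane makes the low-O₂ window
unaffordable for any respiratory-protection budget, a tighter one makes
permeability regulation pointless.  ε = 0 is rejected (the formula is
singular); a sealed membrane is expressed as ε = 10⁻¹².

## Electron transport and the energy closure

Total photosynthetic electron transport (PET) is light-saturating,
proportional to photosystem Fe, and inhibited hyperbolically by respiratory
protection:

    V_PET = φ·Fe_PS · I/(I + k_I) · 1/(1 + V_RP/k_RP_inhib).

Electrons split between linear transport (LPET: 0.5 NADPH and 0.64 ATP per
e⁻, i.e. ATP:NADPH ≈ 1.28, and 0.25 O₂ evolved per e⁻) and alternative
transport (AET: 1.0 ATP per e⁻, no O₂).  At every evaluation the LPET
fraction is solved (bisection on a monotone piecewise-linear mismatch) so
that, after the waterfall below, the leftover ATP and NADPH match carbon
fixation's stoichiometry exactly; when that is impossible within [0, 1] the
fraction is clipped and the stoichiometrically unusable surplus is recorded
as dissipation, keeping production ≡ consumption + dissipation to machine
precision.

Allocation priority: maintenance ATP (e_maint) → photorespiration (up to
its substrate-limited rate) → N₂ fixation (8 ATP + 2 NADPH per N) → carbon
fixation as the residual sink (3 ATP + 2 NADPH per C, plus a 1 ATP per C
carbon-concentrating-mechanism overhead, charged with carbon fixation since
it scales with fixed carbon).  In darkness, ordinary respiration of
carbohydrate (5 ATP per C, 1 O₂ per C) covers maintenance; any remaining
deficit is paid by catabolizing biomass (negative growth), not by raising
an exception.

## Photorespiration

The cap is set by the assumption that PET's total instantaneous ATP
production could be consumed entirely by photorespiration,
V_PR_max = V_ATP/7; the realized rate is Michaelis–Menten in carbohydrate
(k = 0.4 mol C (mol C)⁻¹) and intracellular O₂ (k = 1.92 mol m⁻³), and is
additionally limited by the energy closure.  Stoichiometry per mol C: 7 ATP,
4 NADPH, 3 O₂.  The CO₂ product is dropped (intracellular CO₂ is not
modeled).

## N₂ fixation, respiratory protection, and nitrogenase dynamics

N₂ fixation is capped by the post-photorespiration energy supply scaled by
the cell's N demand (an N-replete cell downregulates fixation; without
this regulation the model drifts into degenerate all-nitrogenase states
that fix N they cannot use), and the realized rate carries
nitrogenase-Fe saturation (k = 20 µmol Fe (mol C)⁻¹) and O₂ inhibition
1 − O₂/(O₂ + 0.02).  Respiratory protection — deliberate wasteful
respiration that draws down intracellular O₂ — follows

    V_RP = v_RP_max · D_N · k_O2_RP/(k_O2_RP + O₂) · CH₂O/(CH₂O + k),

where D_N = k_N/(N + k_N) is the N₂-fixation demand signal (a depleted
fixed-N store signals demand; k_N = 0.1 mol N (mol C)⁻¹ — the smoother
value damps a day-to-day overcompensation oscillation, see "Numerical
choices").  The law rises with demand and falls with O₂, as protection is
futile against a high O₂ background and ramps once O₂ can actually be held
down; it is one swappable function.  The O₂ stock limit (respiration cannot
consume O₂ that is not there) is enforced at the integrator level by
scaling all O₂ consumers to the instantaneous supply when the stock is
exhausted.

Nitrogenase inactivates upon O₂ exposure (rate 2×10⁻³ s⁻¹ · O₂/(O₂+0.05),
i.e. a ~10-minute lifetime at high O₂), moving its Fe to an inactive pool
that recycles to the buffer at 10⁻⁴ s⁻¹.  Synthesis of nitrogenase from
buffer Fe is gated by the demand signal and by low O₂ (k = 0.02 mol m⁻³);
photosystem synthesis follows light, decomposition its complement, so
photosystem Fe leads in the morning and nitrogenase Fe peaks in the
afternoon low-O₂ window.  The four maximal rates (v_RP_max, photosystem
synthesis/decomposition, nitrogenase synthesis) are the calibrated free
parameters.  All Fe transfers draw only from their source pool, are clamped
to pool contents, and conserve total Fe exactly; only uptake
(saturating in dissolved Fe, half-saturation 5000 pM, hence near-linear
over the 20–1,800 pM scenario range) adds Fe.  The uptake scale maps that
range to equilibrium quotas of roughly 25–900 µmol Fe (mol C)⁻¹ at the
model's growth rates.

## Carbon pathway and growth

Fixed carbon enters the carbohydrate store; consumers are
photorespiration, respiratory protection, ordinary respiration, and
carbon-skeleton production (stimulated by carbohydrate, product-inhibited
by skeleton accumulation).  Biosynthesis combines skeletons with fixed N
(0.15 mol N per mol C of biomass; N half-saturation 0.05, smoother than the
skeleton half-saturation 0.1 to damp day-scale N cycling) and sets the
instantaneous growth rate; growth dilutes all per-biomass stores.  The
daily carbon budget decomposes gross fixation into photorespiration,
respiratory protection, ordinary respiration, and biosynthesis (new biomass
plus its store complement); at the periodic state it closes to well under
0.5% by construction of the RK4-consistent integrals, and the residual is
reported.

## Time integration

The slow state advances with fixed-step RK4 (default dt = 60 s; the
acceptance and test drivers use 120–300 s, which the step-halving check
shows is integral-converged to ~0.1%).  Intracellular O₂ is the only fast
variable (exchange + consumption relax it in seconds to minutes) and is
diagnosed quasi-steady within each RK4 stage.  Because respiratory
protection strengthens as O₂ falls, the net O₂ tendency can be bistable;
the solver therefore tracks the branch the cell is on: it marches from the
previous O₂ in the direction of the tendency to the nearest stable root
(Illinois refinement), reproducing the hysteresis of the underlying fast
dynamics, and falls to the O₂ = 0 boundary (with the supply clamp) when
consumption exceeds supply everywhere below.  A fully explicit mode
(sub-stepped Euler at 0.25 s) is provided and is validated against the
quasi-steady mode in the test suite.

A simulation spins repeated 24 h cycles (12 h sine-forced light + 12 h
dark; a photoperiod-only day is configurable) until the daily growth rate
is periodic to 10⁻⁶ d⁻¹ and the full state vector repeats to 0.1%
relative.  The diel map's attractor is usually a fixed point but can be
period-2 (the fixed-N store can overcompensate across days) or weakly
quasi-periodic with sub-percent amplitude; convergence is therefore tested
against both one- and two-cycle lags, and daily quantities are averaged
over a recording block of at least `avg_days` cycles (default 4; the
calibration objective and step-halving checks use 8) to suppress attractor
phase noise.  Non-convergence after 100 cycles returns the last block with
a warning.  The carbon-budget decomposition keeps the recorded block's net
store change as an explicit term, so the closure identity holds to machine
precision even slightly off the attractor.

## Calibration

The four free parameters are chosen to maximize the converged daily growth
rate, separately per permeability mode and dissolved-Fe level: seeded
Latin-hypercube starts, bounded Nelder–Mead per start (derivative-free, as
the growth surface carries small convergence noise), best feasible optimum
kept.  The objective subtracts penalties for residual cycle-to-cycle drift
and for an unclosed recorded-cycle carbon budget, so the optimizer cannot
exploit slowly diverging or hoard-consuming transients whose "growth" is
not a steady phenotype.  The search ranges matter: respiratory protection
is bounded at 1.5×10⁻⁴ mol C (mol C)⁻¹ s⁻¹ (a few times the cell's peak
carbon-fixation capacity) because far larger values turn the O₂ balance
into a sub-hourly relaxation oscillator rather than a diel strategy.  The
shipped table was produced with the recorded seed and profile and can be
re-derived with the `calibrate` CLI; experiment drivers use the exact
per-level calibration where shipped and interpolate the four parameters in
log-Fe between levels otherwise.  Growth maximization is an optimality
assumption — the organism is taken to operate its protection and Fe
turnover machinery near the growth optimum under each condition.

## The photorespiration-substitution replay

One scenario experiment replays the dynamic-permeability case while
forcing the fixed-permeability case's photorespiration trajectory onto it.
The transplant imposes the donor's photorespiratory carbon, ATP and NADPH
losses (still capped by the replay's instantaneous energy supply); the O₂
sink of photorespiration remains the replay's own kinetic oxygenation
rate.  Transplanting the O₂ sink as well would smuggle in an O₂-management
intervention — three O₂ consumed per carbon, without the
electron-transport inhibition that respiratory protection carries — and
the experiment would then measure a spurious benefit of morning O₂
scrubbing instead of the energetic burden of elevated photorespiration,
which is what it is designed to isolate.

## Synthetic observations

The fixtures generator emulates sparse laboratory sampling of a diel
culture: photosystem Fe, nitrogenase Fe (5 equally spaced light-period
samples by default) and the daily growth rate, with mean-preserving
multiplicative lognormal noise of configurable CV (default 0.1, a typical
analytical spread for cellular Fe quotas), seeded and reproducible.  It
reproduces sampling sparsity and multiplicative measurement error; it does
not emulate biological replicate variability, non-stationary cultures, or
instrument drift, so passing fit metrics show self-consistency of the
pipeline, not field realism.  Goodness of fit uses R² and the reliability
index RI = exp(√(mean(ln(obs/model)²))) — the root-mean-square form, whose
value is 1.0 at perfect agreement and symmetric in its arguments; a
`literal_form` flag drops the square root for comparison with sources that
print the formula without it.

## Numerical choices and degenerate inputs

* Energy-closure bisection: 44 iterations (f to ~6×10⁻¹⁴); closure holds
  identically regardless, the precision only sets the dissipation split.
* Quasi-steady O₂ root: Illinois to 10⁻¹² + 10⁻¹⁰·O₂; bracket expansion
  factor 1.6 from the warm start.
* Negative stores produced by an RK4 step are clipped to zero and counted;
  substrate Michaelis–Menten factors make such events rare and small.
* Zero total ATP+NADPH demand with positive PET routes all electrons
  through AET (logged); zero observation variance makes R² undefined
  (NaN, logged); ε = 0 raises; non-finite fluxes raise naming the term.

## Limitations

* Colony microenvironments, boundary-layer chemistry beyond the single Lb
  term, and intracellular CO₂/carbonate chemistry are out of scope.
* The rate laws that the antecedent models do not state openly (exact PET
  form, respiratory-protection law, Fe translocation kinetics, maintenance
  costs) are represented by the documented Michaelis–Menten forms above;
  each is a single swappable function, and the geometry and ρ_C defaults
  are flagged uncalibrated.
* The model describes one trichome; no stochastic forcing, no
  colony-to-population scaling, no nitrogenase isoforms, and no separate
  Mehler/flv O₂ uptake fluxes.
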