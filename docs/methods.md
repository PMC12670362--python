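# Methods

This note documents the model as implemented, the parameter choices behind
the shipped defaults, the synthetic-data generator, and the numerical and
design decisions a user extending the package should know about.

## Model structure and assumptions

The organism is a standard three-state DEB individual (reserve `E`,
structure `V`, maturity/reproduction buffer `R`) with first-feeding starting
at birth and a single, static environment per life-history run. Three
assumptions are relaxed relative to the constant-corrected standard model:

1. **Differential thermal scaling.** Assimilation scales with a
   Sharpe–Schoolfield factor `q_A(T)` (Arrhenius activation divided by a
   high-temperature deactivation term), all other rates (`v̇`, `ṗ_M`,
   `k̇_j`) with the pure Arrhenius factor `q_M(T)`. `q_A` is deliberately
   *not* renormalised at the reference temperature; the deactivation term is
   already active at 20 °C, so `q_A(293.15 K) ≈ 0.903`. The ratio
   `q_A/q_M = 1/(1 + e^(E_d(1/kT_d − 1/kT)))` falls monotonically with
   temperature and passes exactly ½ at `T_d`; it acts like a
   temperature-dependent discount on effective food level, which is the
   engine of the warm-side pattern collapse.
2. **Temperature-dependent allocation.** `κ(T)` declines sigmoidally from
   0.7 to 0.6 around an inflexion `T̂` with stiffness `λ`. With the default
   stiff sigmoid the allocation shift is concentrated in a narrow band just
   below the thermal optimum; that band is where the classic TSR (mass and
   age both falling) is expressed.
3. **Dual puberty threshold with an observation delay.** Puberty requires
   both `R ≥ R_p` (energetic maturity) and `V ≥ V_p` (a minimal structural
   size that prevents implausibly small maturation at extremes). The first
   clutch is laid one adult-instar delay `δ(T)` later; observed
   age-at-maturity includes this delay, and observed mass includes the
   growth and buffer accumulated during it.

### The instar-delay convention

Two conventions for `δ(T)` are implemented (`delta_convention`):
`as_printed` (default), `δ = δ* · q_M(T)`, and `rate_scaled`,
`δ = δ*/q_M(T)`. Both give δ = 2 d at 20 °C. The default is deliberate and
load-bearing: the growth and clutch energy accumulated during a delay that
*lengthens* with warming is the only term in the model that makes
mass-at-maturity increase with temperature on the cold side, i.e. it creates
the reverse-TSR region. Under `rate_scaled` the mass reaction norm is
monotonically decreasing in temperature for every parameterisation we
explored and the cold r-TSR band never appears. A duration that grows with
temperature is physiologically unusual, which is why the alternative is kept
behind a flag, but the default reproduces the intended response geography.

### Post-puberty buffer accounting

The single printed ODE for `R` is kept across the juvenile→adult transition:
maturity maintenance keeps draining the full buffer (`−k̇_j q_M R`). The
documented alternative (`adult_maintenance="frozen"`) drains only the frozen
maturity level `R_p`. Clutch energy at laying is `max(R − R_p, 0)`.

## Default parameters

Fixed by the model description: `E_a` = 0.65 eV, `E_d` = 1.89 eV,
`T_d` = 302.15 K, `T*` = 293.15 K, `k` = 8.617×10⁻⁵ eV K⁻¹, κ ∈ [0.6, 0.7],
`ṗ_M` ∈ [330, 740] J cm⁻³ d⁻¹ and `k̇_j` ∈ [0.05, 0.1] d⁻¹ spanning the
food-quality axis, `δ*` = 2 d, `d_m` = 19×10⁴ µg cm⁻³,
`d_e` = 25×10⁻³ J µg⁻¹.

The remaining constants are not published for this configuration and were
chosen once, by a scored search, so that the default *D. magna*-like
organism reproduces the qualitative response geography (r-TSR → TSR →
non-TSR ordering; the window contractions and shifts under food, quality
and variance constraints; survival in all factorial treatments except the
hot/low-food/low-quality cells; the combined-degradation breakdown), with
trait magnitudes in the biologically familiar range (maturity at 4–21 d,
hundreds of µg dry mass):

| parameter | value | units | role |
|---|---|---|---|
| `ṗ_AM`  | 200   | J cm⁻² d⁻¹ | maximum surface-specific uptake |
| `k_s`   | 0.3   | mgC L⁻¹    | half-saturation food concentration |
| `v̇`    | 0.12  | cm d⁻¹     | energy conductance |
| `E_G`   | 1200  | J cm⁻³     | volume-specific cost of structure |
| `T̂`    | 22.0  | °C         | κ-sigmoid inflexion |
| `λ`     | 2.8   | °C⁻¹       | κ-sigmoid stiffness |
| `R_p`   | 1.2   | J          | maturity energy threshold |
| `V_p`   | 1.5×10⁻⁴ | cm³     | minimal structural volume at puberty |
| `m_0`   | 7     | µg         | neonate dry mass |
| `e0_frac` | 0.35 | –         | neonate reserve mass fraction |
| horizon | 100   | d          | failure deadline for the first clutch |

The neonate starts with `V₀ = m₀(1−e0_frac)/d_m`, `E₀ = m₀·e0_frac·d_e`,
`R₀ = 0`. Every value is overridable through a flat TOML/YAML parameter
file; unknown keys are rejected.

With these defaults the reference-context (X = 3 mgC L⁻¹, high quality,
constant temperature) TSR window sits at ≈ 21–23 °C, the r-TSR band extends
from ≈ 6 °C up to it, and growth rate declines above ≈ 23.5 °C. Absolute
trait values are on the heavy side for *D. magna* (≈ 700 µg with clutch at
20 °C); the package's claims are about response *patterns* and internal
consistency, not about matching any particular clone's absolute masses.

### The κ-stiffness sensitivity sweep

`patterns.lambda_sensitivity` reports, per stiffness value, the TSR window,
the width of the near-flat mass-slope region inside it, and the steepest
normalised mass decline inside it. Under the shipped calibration, larger λ
concentrates the allocation shift and steepens the maximal decline; it does
*not* widen a flat segment, because the mid-range mass norm below the
transition is instar-driven rising (that rise is the r-TSR band) rather than
near-flat. Calibrations whose mid-range norm is flat-but-slightly-negative
would instead show the "broader stable-size range" phrasing sometimes used
for this sensitivity; both readings agree that λ controls how sharply size
responds to warming inside the window.

## Forcing and covariation

Temperature is constant or a diurnal square wave (warm half-period first;
the phase is configurable only through the regime's period/mean, and the
solver is restarted at every half-period switch so no discontinuity is
stepped over). Under fluctuation the adult-instar delay uses the regime's
mean temperature by default; an `instar_clock="instantaneous"` alternative
accumulates instar development as ∫dt/δ(T(t)).

Covariation rules change one factor linearly with warming —
`baseline · (1 + rate·ΔT/100)`, linear, not compounding, so ±6.25 % °C⁻¹
over 4 °C is exactly ±25 %. Food quantity and amplitude covary on their own
scales. The *quality* rule covaries the quality-controlled quantities, i.e.
the maintenance costs themselves: a quality decline of r % °C⁻¹ raises both
`ṗ_M` and `k̇_j` by r % °C⁻¹ (clamped to the admissible quality range).
Scaling the abstract quality level in [0, 1] instead would translate a
nominal "25 %" scenario into only a ≈ 10 % cost change and visibly weakens
every covariation result; the cost-scale reading also makes the
combined-degradation scenario (food −6.25, quality −6.25, amplitude
+6.25 % °C⁻¹ over 18→22 °C) end with both smaller mass and older age, the
TSR-breakdown signature.

## Numerical choices

* Integration: `scipy.integrate.solve_ivp` (RK45), rtol 10⁻⁸, per-state
  atol (10⁻¹⁰, 10⁻¹³, 10⁻¹⁰) matched to the J / cm³ / J scales. Halving the
  tolerances moves traits by < 0.01 %.
* Events: puberty is the upward root of `min(R − R_p, V − V_p)`; failure
  events are reserve exhaustion (`E` crossing 0 downward) and shrinkage of
  `V` below 10 % of its running maximum. An individual that has not laid a
  clutch by the horizon is flagged failed with reason `horizon` — this is
  what produces the no-maturity (white) regions of the pattern maps.
* Slopes: central finite differences on interior grid cells, one-sided at
  the edges, NaN wherever the cell or a stencil neighbour failed.
  Classification uses slopes on median-normalised traits with a unit-free
  tolerance ε = 10⁻³ °C⁻¹: growth decline ⇒ non-TSR; mass and age both
  falling ⇒ TSR; mass rising with age falling ⇒ r-TSR; otherwise flat.
  TSR windows are reported on interior cells only.
* Scenario endpoint classification uses endpoint-minus-start differences on
  the same normalised scale (the per-point local labels remain available
  from the trajectory frame).

## Synthetic experiment and validation

The generator emulates the 2×2×2×2 factorial design (20/28 °C × 0/±5 °C ×
3/0.4 mgC L⁻¹ × high/low quality; 4 jars × 8 individuals). Each treatment's
deterministic model prediction is the expected phenotype; observations are
`prediction × exp(jar effect + individual noise)` with jar effect
~ N(0, jar_sd²) and individual noise ~ N(0, log(1+cv²)), defaults
cv = 0.1 and jar_sd = 0.05 — chosen so treatment effects dominate
within-treatment spread, as in a well-run growth experiment; they are
placeholders, not estimates of any real dataset's variance. Ages are rounded
to the daily census (minimum 1 d). The high-temperature × low-food ×
low-quality treatments are emitted entirely as died-before-maturity, and the
generator treats a model maturation failure in any *other* treatment as an
error (the parameterisation would contradict the emulated design).

What passing tests on these data do and do not show: they verify the
pairing, exclusion and metric arithmetic end-to-end and that the noise model
is unbiased on the multiplicative scale; they cannot certify the model
against real animals, since the observations are generated by the model
itself. Real trait tables with the same columns can be fed to
`thermodeb compare` directly.

Validation metrics: `MBE = mean(pred − obs)` (positive = systematic
overestimation), `RMSE = sqrt(mean((pred − obs)²)) ≥ |MBE|`, each optionally
normalised by the mean observed value of its scope (per-treatment scopes
normalise by the treatment mean by default; a flag switches to the grand
mean). Dead individuals never enter numeric metrics; treatments where the
model also fails count as agreement-on-failure and are likewise excluded.

## Known limitations

* Single individual, single clutch: no multi-clutch reproduction schedule,
  no population dynamics, no inter-individual physiological variation
  (stochasticity lives entirely in the synthetic-experiment observation
  layer).
* No parameter estimation: the package ships a calibrated default organism
  and a config surface, not a fitting routine.
* Square-wave and constant regimes only; no stochastic or seasonal forcing.
* Starvation physiology is minimal (shrinkage allowed, death below a fixed
  fraction of peak structure); there is no maintenance depression or
  reserve-threshold κ switching.
* The quality axis compresses a multidimensional nutritional reality
  (fatty acids, sterols, stoichiometry) into one maintenance-cost scalar.
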