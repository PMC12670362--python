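# thermodeb

Bioenergetic simulation of ectotherm size- and age-at-maturity under joint
temperature, thermal-variance and nutrition forcing.

Ectotherms usually mature smaller, younger and faster-growing as mean
temperature rises — the temperature-size rule (TSR). In nature, warming
rarely comes alone: food becomes scarcer, its quality (polyunsaturated fatty
acid and sterol content) declines, and daily temperature swings grow. This
package implements a Dynamic Energy Budget (DEB) model, parameterised for
the water flea *Daphnia magna*, that predicts when the TSR holds, reverses
(bigger at warmer temperatures, "reverse-TSR") or breaks down (slower growth,
"non-TSR") across such environmental contexts — and what happens when those
contexts *covary* with warming. It is aimed at ecophysiologists and
life-history modellers who want a mechanistic, testable account of
size-at-age responses instead of curve fitting.

## The model

State variables: reserve energy `E` (J), structural volume `V` (cm³) and the
cumulative maturity investment / reproductive buffer `R` (J), driven by

```
dE/dt = ṗ_A − ṗ_C                       assimilation minus mobilisation
dV/dt = (κ ṗ_C − ṗ_S) / E_G             growth from the somatic share
dR/dt = (1 − κ) ṗ_C − k̇_j R            maturation minus maturity maintenance
```

with `ṗ_A = ṗ_AM V^(2/3) f_X`, the Holling type-II response
`f_X = X/(X+k_s)`, maintenance `ṗ_S = ṗ_M V`, and the standard DEB
mobilisation flux `ṗ_C = E (v̇ E_G V^(2/3) + ṗ_S)/(E_G V + κ E)`.

Three departures from standard DEB create the thermal life-history
geography:

* **Uptake vs. metabolism.** Assimilation carries a unimodal
  Sharpe–Schoolfield factor `q_A` (activation energy `E_a` = 0.65 eV,
  deactivation `E_d` = 1.89 eV, 50 % deactivation at `T_d` = 302.15 K) while
  conductance and the maintenance rates carry a monotone Arrhenius factor
  `q_M`. Warming therefore erodes the energy balance near and above 29 °C.
* **Plastic allocation.** The somatic allocation fraction is a decreasing
  sigmoid of temperature, `κ(T) = κ_max − (κ_max − κ_min)/(1 + e^(−λ(T−T̂)))`
  between 0.7 (cold) and 0.6 (warm).
* **Observed vs. energetic maturity.** Puberty fires when both thresholds
  `R ≥ R_p` and `V ≥ V_p` are met; eggs appear one first-adult-instar delay
  `δ(T) = δ_T* e^(E_a(1/kT* − 1/kT))` later (δ = 2 d at 20 °C), which is
  what an observer scores as maturity.

Food quality acts through maintenance costs: `ṗ_M` spans 330–740 J cm⁻³ d⁻¹
and `k̇_j` 0.05–0.1 d⁻¹ between the high-quality (*Cryptomonas*-like) and
low-quality (*Synechococcus*-like) endpoints. Thermal variance is a diurnal
square wave `T(t) = T̄ + A·sgn(sin 2πt)`. Traits are extracted at clutch
laying: dry mass (structure + reserve + clutch via the conversion densities
`d_m` = 19×10⁴ µg cm⁻³, `d_e` = 25×10⁻³ J µg⁻¹), observed age, and the
juvenile specific growth rate `g = ln(m_M/m_0)/a_M`.

On top of the simulator the package provides:

* `patterns` — temperature × factor sweeps, local reaction-norm slopes, and
  per-cell classification into TSR / r-TSR / non-TSR / flat / no-maturity,
  with TSR-window extraction and a κ-stiffness sensitivity sweep;
* `scenarios` — age–size phase-space trajectories where food quantity,
  food quality (via maintenance costs) and thermal amplitude drift linearly
  with warming (±6.25 % per °C over three 4 °C windows);
* `synthetic` — a generator emulating a 2×2×2×2 factorial growth experiment
  (20/28 °C × constant/±5 °C × 3/0.4 mgC L⁻¹ × high/low quality, 4 jars × 8
  individuals) with lognormal jar and individual noise and daily age census;
* `validation` — RMSE and mean bias error (MBE, positive = overestimation),
  raw and normalised by the mean observed value, overall and per treatment.

## Worked example

Simulate one individual per condition at high food and quality:

```python
from thermodeb import DEBParameters, EnvironmentSpec, simulate_individual

params = DEBParameters()
for T, A in [(20, 0), (28, 0), (20, 5), (28, 5)]:
    env = EnvironmentSpec.constant(T, X=3.0, quality_level=1.0, amplitude=A)
    res = simulate_individual(params, env)
    print(T, A, [round(x, 3) for x in res.traits])
```

prints (mass µg, observed age d, growth rate d⁻¹):

```
20 0 [702.716, 8.194, 0.563]
28 0 [623.376, 8.19, 0.548]
20 5 [495.045, 7.681, 0.554]
28 5 [420.2, 9.11, 0.449]
```

Constant warming from 20 to 28 °C shrinks mass with little change in age —
the warm flank of the TSR window. Adding a ±5 °C diurnal swing at 28 °C
(half of every day at 33 °C, above the enzyme-deactivation temperature)
cuts mass by a third and *delays* maturity: thermal variance pushes the
animal past its thermal optimum and the TSR response collapses.

The same runs from the shell:

```bash
thermodeb simulate --tmean 28 --amp 5 --food 3 --quality 1
thermodeb grid --factor food --out grid.csv         # pattern map (label per cell)
thermodeb scenario --window 18,22 --rule X:-6.25 --rule quality:-6.25 \
                   --rule amplitude:+6.25           # combined-degradation arrow
thermodeb synth --seed 42 --out obs.csv             # synthetic factorial data
thermodeb compare --obs obs.csv --out report.csv    # RMSE / MBE report
```

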