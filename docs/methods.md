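# Methods

`trpgating` models thermosensitive TRP-channel gating as an **alternating
renewal (semi-Markov) process**: the channel visits a small chain of kinetic
states (C ↔ O, or C1 ↔ C2 ↔ O) and the time spent in each state is an
independent draw from that state's residence-time distribution. When every
residence time is exponential the process collapses to the familiar Markov
state model; non-exponential dwell laws give the process memory, which is
the behaviour observed in thermosensitive channels driven out of
equilibrium.

## The gating process

A two-state trajectory is the sequence C →(θ₁) O →(θ₂) C →(θ₃) O …, with
each θᵢ drawn from the occupied state's dwell law. Four dwell-law families
are implemented, each with density ψ(t), survival Φ(t), hazard ψ/Φ, mean and
Laplace transform ψ̂(s):

| family | parameters | role |
|---|---|---|
| exponential | rate λ | Markov limit (flat hazard) |
| gamma | shape κ, scale θₛ | multi-step exits; rising hazard for κ>1 |
| stretched exponential | scale θₛ, stretch b ∈ (0,1] | Kohlrausch "broad distribution of rates" |
| pareto | tail α, minimum t_m | power-law tail; infinite mean for α ≤ 1 |

An infinite pareto mean (α ≤ 1) is reported as `math.inf` (and
`finite_mean()` raises `InfiniteMeanError`); it is never an overflow.

In the three-state chain the middle closed state C2 exits to **either** C1
or O. The main-scheme definition does not pin down the semi-Markov kernel,
so the package uses the standard competing-risks construction: the dwell is
drawn from C2's own law and the destination is chosen with a fixed branch
probability `branch_open_prob` = k(C2→O)/(k(C2→O)+k(C2→C1)). This is a
deliberate, documented simplification.

## Occupancies: three routes that must agree

1. **Monte Carlo** — trajectories are sampled by inverse-CDF draws; one root
   seed spawns an independent child stream per trajectory
   (`numpy.random.SeedSequence.spawn`), so results are bitwise reproducible
   and invariant under any parallel partition of the work. The final dwell
   of each trajectory straddles the horizon and is treated as
   right-censored: it is excluded from dwell statistics to avoid
   length-biased underestimates.
2. **Closed form** — the two-state Markov master equation
   p_O(t) = p_∞ + (p₀ − p_∞)e^−(k_o+k_c)t, p_∞ = k_o/(k_o+k_c).
3. **Generalized master equation in the Laplace domain** — for arbitrary
   dwell laws, alternating-renewal theory gives
   P̂_O(s | start C) = ψ̂_C(1−ψ̂_O) / [s(1−ψ̂_Cψ̂_O)] (and
   (1−ψ̂_O)/[s(1−ψ̂_Cψ̂_O)] when starting open). The final-value theorem
   recovers the renewal-reward limit ⟨τ_O⟩/(⟨τ_C⟩+⟨τ_O⟩). These formulas
   are re-derived from standard renewal arguments.

Numerical inversion uses the fixed-Talbot contour by default (needs the
transform on the complex plane — available in closed form for exponential
and gamma laws) with Gaver–Stehfest as a real-axis fallback for
quadrature-defined transforms. Every point is computed at two internal
orders; the pair must agree to the accuracy target (relative to max(|f|,1)),
otherwise a `LaplaceInversionError` with diagnostics is raised. Talbot
passes the closed-form validation suite (e^−at, t, 1) at 1e-6; Stehfest is
limited to ~1e-3 and documented as such.

**Long-time (Tauberian) behaviour.** The small-s expansion of ψ̂ classifies
the relaxation: two exponential laws give exponential relaxation at rate
k_o+k_c; a pareto closed law with α ∈ (0,1) has
ψ̂_C(s) ≈ 1 − Γ(1−α)(t_m s)^α, so the closed-state survival decays as
t^−α and, the mean closed time being infinite, the open occupancy itself
decays like t^(α−1).

## Thermodynamics

Rates follow the Eyring/attempt-frequency form k = ν₀·exp(−ΔG‡/RT). All
energies are **molar** (J/mol, gas constant R); conversion helpers to
per-molecule k_B units live in `trpgating.constants`. Temperature is kelvin
everywhere internally; Celsius is converted only at I/O boundaries. A small
voltage driving enters linearly, k₀(1 − βV_s), clamped at zero with a
warning when the first-order expansion is pushed outside its validity.

The temperature sensitivity is carried by the open/closed free-energy
asymmetry

    ε(T) = ΔH − TΔS + RT·ln(1 + k_c1(T)·τ_r),

with the **sign convention (fixed here): ε > 0 favours the closed state**,
so P_O = 1/(1 + e^{ε/RT}) and P_O = ½ at the half-activation temperature
T\* = ΔH/ΔS when the memory term vanishes. ΔH, ΔS > 0 gives a
heat-activated (TRPV1-like) channel, ΔH, ΔS < 0 a cold-activated
(TRPM8-like) one — the same expression captures both polarities. An
equivalent "barrier form" ε = ΔG_O(V₀) − ΔG_C(V₀) + RT·ln(1+k_c1τ_r) is
provided; the two agree exactly when the barrier difference equals ΔH − TΔS,
and keeping that consistency is the caller's responsibility (the source
formulation is sign-ambiguous on this point).

**The memory term.** k_c1 is the exit rate of the deep closed state and
τ_r a relaxation time of the environment. A rate constant carries Eyring
temperature dependence, so the package gives k_c1 an Arrhenius law

    k_c1(T) = k_c1(T_ref)·exp[−(ΔH_c1/R)(1/T − 1/T_ref)],

with ΔH_c1 **fixed by configuration** (default 150 kJ/mol, the scale of
reported TRP gating enthalpies; T_ref = 310 K). This choice matters: with a
temperature-independent product k_c1τ_r the memory term RT·ln(1+k_c1τ_r) is
affine in T and exactly collinear with −TΔS, so a memoryless model absorbs
it completely and no experiment could ever distinguish the two. The
Arrhenius temperature dependence makes the term curved in T and the
distinction testable. Setting `dH_c1 = 0` (the `ThermoParams` default)
recovers the constant-product convention.

**Temperature coupling of non-exponential laws.** Temperature rescales a
law's time axis so its mean equals 1/k(T), leaving shape parameters fixed.
This is the minimal coupling; it is an assumption, not a derived result.

## G–V / G–T analysis

Chord conductance G = I/(V − E_rev) (records at the reversal potential are
flagged, not divided; E_rev defaults to 0 mV for symmetric-Na⁺ solutions).
G–V curves at fixed T are fitted with a Boltzmann
g = g_max/(1+exp((V½−V)/s)); flat inputs produce an explicit `FitFailure`
report instead of runaway parameters. G–T curves at fixed V feed a van't
Hoff regression of ln K on 1/T with K = p/(1−p): slope −ΔH/R, intercept
ΔS/R, T\* = ΔH/ΔS (reported as undefined when ΔS = 0). Probabilities are
clipped to [1e-6, 1−1e-6] before the logit — the clip changes |ln K| by at
most ~13.8 on an affected (saturated) record, and the number of clipped
records is reported. The regression is ordinary least squares by default
(no weighting scheme is implied by the data source); per-point weights are
accepted. Q10 = (k₂/k₁)^{10/(T₂−T₁)}.

## Fitting and identifiability

`EquilibriumGatingModel` predicts p_open(T, V) through ε(T) and an optional
multiplicative Boltzmann voltage factor (fixed, not fitted; normalized to 1
at +160 mV so the top of the ladder reports the bare open probability). The
loss is weighted least squares (per-record sd when present), minimized by
Levenberg–Marquardt from 8 seeded multi-starts: one start from a logit
regression, the rest drawn jointly so that T\* = ΔH/ΔS falls inside the
data's temperature span — the ΔH/ΔS ridge makes independent draws useless.
Covariance is σ²(JᵀJ)⁻¹ with t-based confidence intervals; AIC/BIC are
Gaussian, and the small-sample AICc is the default ranking criterion in
`compare_models` (every realistic G–T dataset has n/k < 40).

Parameter accounting per scheme (raw rate coefficients vs identifiable):
markov_2 (2, 2); markov_3 (6, 4) — with two closed states, six rate
coefficients define the scheme but only four independent parameters are
determinable from data, so three-state fits keep the C1↔C2 gap fixed by
configuration; nonmarkov_2 (4, 4) — two means plus two shapes;
nonmarkov_3 (7, 5) — three means, three shapes and the C2 branch
probability, of which aggregation of the closed states leaves five
determinable (package convention). ν₀ is always fixed: the
barrier/prefactor product is not identifiable. Requests that exceed the cap
raise `IdentifiabilityError` with an explanation rather than silently
fitting.

Dwell-time event lists are fitted per state by maximum likelihood
(closed-form for exponential and pareto, `scipy.stats` MLE for gamma and
Weibull), reporting log-likelihood, AIC and a Kolmogorov–Smirnov distance;
fewer than 50 events warns of wide intervals but does not fail.

## The synthetic world

The generator emulates the *structure* of whole-cell thermosensitivity
recordings: a −120…+160 mV ladder in 20 mV steps, 8 temperatures, and
normalized conductance g(T,V) = P_open(ε(T),T)·b(V) with truncated
(clipped to [0,1]) Gaussian noise, homoscedastic sd = 0.02 by default
(heteroscedastic sd ∝ g(1−g) optional). Default profiles:

* `trpv1_like`: ΔH = 200 kJ/mol, ΔS = 635 J/(mol·K) → T\* ≈ 315 K, grid
  301–329 K. Half-activation just above 42 °C, the noxious-heat threshold.
* `trpm8_like`: ΔH = −150 kJ/mol, ΔS = −520 J/(mol·K) → T\* ≈ 288 K, grid
  275–303 K (cool/menthol range).

These are **synthetic conventions** with the right polarity and steepness —
not fitted values from any real recording — and the metadata of every
generated dataset says so. What a green round-trip test establishes is that
the analysis inverts the generator's stated world; it does not validate the
model against real channels, instrument filtering, leak/rundown artefacts
or cell-to-cell variability, none of which are simulated.

The model-discrimination experiment (memory product k_c1τ_r = 2 at T_ref)
uses 10 temperatures over 295–331 K with 8 replicates and sd = 0.02: an a
priori power calculation showed the memory curvature is ~1–2% in g, so an
unreplicated 8-point design cannot resolve it, while the replicated design
identifies the memory model in ≈100% of noise realizations. That design,
chosen before the tests were frozen, is the stated world of the
discrimination claim.

## Numerical choices and limitations

* Geometric (log-spaced) time grids by default, resolving fast relaxation
  and slow tails together.
* Laplace quadrature transforms (stretched-exponential, pareto) are defined
  only on Re(s) ≥ 0; use Stehfest inversion for those, at ~1e-3 accuracy.
* Dwell statistics report effective rates as 1/⟨τ⟩. The source material
  at one point equates a rate with a mean residence time; dimensional
  consistency forces the reciprocal reading used here.
* The equilibrium fit sees only p_open; it cannot recover kinetic
  quantities (ν₀, individual barriers), which is why those are fixed.
* The three-state Laplace-domain solution is not implemented (two-state
  only); three-state occupancies come from Monte Carlo.
* No missed-event correction, raw-trace idealization, ligand binding, or
  full charge-movement voltage gating.
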