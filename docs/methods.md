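# Methods

`radiolysis-irt` simulates the *chemical stage* of low-LET water radiolysis —
the 10⁻¹² to 10⁻⁶ s window in which the reactive species formed around energy
deposition sites (spurs) diffuse and react before their distribution
homogenizes — and reports time-resolved radiation chemical yields
(G-values, molecules per 100 eV) as functions of temperature (25–150 °C) and
pH (5–9).  This note documents the model, its parameters, the numerical
choices, and what the validation does and does not demonstrate.

## Model overview

The pipeline has three layers:

1. **Parameter layer** (`parameters`): every condition-dependent chemical
   input is evaluated once per (temperature, pH) condition and frozen into a
   `ChemicalTable` — rate constants k(T), diffusion coefficients D(T), the
   Onsager radius r_c(T), water density ρ(T) along the liquid–vapour
   coexistence curve, and the background concentrations [H3O⁺] = 10^(−pH),
   [OH⁻] = K_w/[H3O⁺].
2. **Initial condition** (`spur`): a synthetic spur generator draws the
   species identities and 3D positions at ~1 ps, emulating what a
   track-structure physical + physico-chemical simulation hands to the
   chemistry stage.
3. **Kinetics** (`irt`): the independent-reaction-times (IRT) method samples
   one tentative reaction time per reactive pair from its first-passage
   distribution and realizes events in global time order, without simulating
   trajectories.  A step-by-step Brownian-dynamics simulator (`sbs`) serves
   as a brute-force oracle on toy configurations.

## Chemical parameters

### Reaction scheme

Thirteen reactions — within the 10–14-reaction window known to be sufficient
below 1 μs for low-LET radiolysis — are packaged in `data/reactions.csv`:
nine pairwise spur reactions,

    e_aq + e_aq → H2 + 2 OH⁻        k₂₅ = 5.5e9  M⁻¹s⁻¹
    e_aq + OH   → OH⁻               k₂₅ = 2.95e10
    e_aq + H    → H2 + OH⁻          k₂₅ = 2.65e10
    e_aq + H3O⁺ → H                 k₂₅ = 2.11e10
    e_aq + H2O2 → OH + OH⁻          k₂₅ = 1.41e10
    OH + OH     → H2O2              k₂₅ = 4.4e9
    OH + H      → (H2O)             k₂₅ = 1.44e10
    H + H       → H2                k₂₅ = 1.2e10
    H3O⁺ + OH⁻  → (2 H2O)           k₂₅ = 1.43e11

plus four background-scavenging channels in which one reactant (H3O⁺, OH⁻ or
H2O) is homogeneously distributed: e_aq + H3O⁺(bg), H + OH⁻(bg) → e_aq,
e_aq + H2O(bg) → H + OH⁻, and OH⁻ + H3O⁺(bg).  Room-temperature values are
the GEANT4-DNA chemistry defaults, to which the temperature laws converge
exactly at 25 °C.  The OH + OH⁻(bg) channel is deliberately omitted: its
product O•⁻ lies outside the 8-species set and belongs to the extended
homogeneous-stage scheme that is out of scope below 1 μs.

Stoichiometry is validated at load time: charge must balance exactly and the
H/O atom residual of every reaction must be a whole number of water
molecules (water is not tracked as a discrete product).

### Temperature laws

Rate constants and diffusion coefficients carry per-row temperature laws in
the data files, valid on [25, 150] °C with hard domain errors outside:

* `arrhenius`: X(T) = X₂₅ · exp[(Ea/R)(1/298.15 − 1/T)], with activation
  energies (kJ/mol) taken from high-temperature water-radiolysis rate
  compilations: ~20 kJ/mol for hydrated-electron reactions and its
  diffusion, 8–16 kJ/mol for the radical–radical channels, ~9 kJ/mol for the
  ion recombination, 31–38 kJ/mol for the slow water/OH⁻ channels; diffusion
  activation energies near water self-diffusion (17 kJ/mol) for neutral
  species and smaller (10.5–12.6 kJ/mol) for the Grotthuss-assisted ions.
* `linlog`: log₁₀ k(t) = log₁₀ k₂₅ + c·(t − 25).  Used for OH + OH, whose
  observed rate *decreases* mildly with temperature
  (c = −6×10⁻⁴ per °C, ≈ −16% over the range); this single decreasing law
  is what drives G(OH) up and G(H2O2) down with temperature.

Both files are plain CSV and user-replaceable; an override file (same
dialect) can replace or extend individual reactions by id, and out-of-table
reactions must declare their kinetics class explicitly because the sampling
formula depends on it.

### Water properties

* Density: quartic fit ρ(t) = 0.999 + 1.094e−4·t − 7.397e−6·t² +
  2.693e−8·t³ − 4.714e−11·t⁴ g/ml (coexistence curve); 0.9975 at 25 °C,
  0.916 at 150 °C (steam tables give 0.917 — the 0.001 g/ml residual is
  fit/source rounding).  The density feeds the molar water concentration
  used by the H2O background channel.
* Permittivity: a Malmberg–Maryott-form cubic for saturated liquid water,
  with the constant term anchored so ε(25 °C) = 78.386 and hence
  r_c(25 °C) = 0.715 nm exactly.
* Onsager radius: r_c = e²/(4π ε0 ε k_B T).  Because ε(T)·T *decreases* over
  25–150 °C for saturated water, r_c *increases* (0.715 → 0.893 nm): Coulomb
  effects strengthen in hot water.  This is the standard behaviour of the
  correlation; we note it explicitly because qualitative statements to the
  contrary circulate.
* K_w is held at its 25 °C value (10⁻¹⁴) at all temperatures: the
  temperature dependence of water self-dissociation, and ionic-strength
  effects at high acidity, are deliberately out of scope; pH and temperature
  are treated as independent inputs.

### Derived per-reaction quantities

For pair channels the Smoluchowski radius is R = k/(4π N_A D) with D the sum
of the reactant diffusion coefficients (internally nm²/ns; conveniently
1×10⁻⁹ m²/s = 1 nm²/ns, and molar rate constants convert to particle-pair
units by 1 M⁻¹s⁻¹ = 1.66054×10⁻⁹ nm³/ns).  For background channels the
scavenging capacity k_obs·[bg] (s⁻¹) acts as a pseudo-first-order rate.

## The spur model

The generator (defaults in `data/spur_model.yaml`) emulates the pre-chemical
hand-off with the classic spur-diffusion-model parameterization for fast
electrons: fixed 62.5 eV per spur, initial yields per 100 eV at ~1 ps of
e_aq 4.78, OH 5.70, H 0.62, H2 0.15, H3O⁺ 4.78, and isotropic Gaussian
spatial spreads of 2.3 nm rms per axis for the hydrated electron and 0.85 nm
for everything else.  Counts are drawn per *water-decomposition channel*
(H2O → e_aq + OH + H3O⁺; H2O → H + OH; 2 H2O → H2 + 2 OH), each Poisson
with mean yield × E/100, so that every spur is exactly charge neutral and
exactly balanced between reducing and oxidizing equivalents.  Two
consequences:

* the material-balance diagnostic G_red = G_ox holds *identically* (to
  floating point) at every time, because every reaction in the scheme also
  conserves the redox difference — the reported discrepancy percentages
  measure bookkeeping integrity, not generator shot noise;
* the measured initial G at the grid start equals the configured yields only
  when chemistry is switched off, since spur reactions begin at 1 ps, before
  the 10⁻³ μs observation window opens.

What the generator does *not* emulate: track-segment geometry (spurs are
isolated; no inter-spur overlap), the energy-per-spur distribution (fixed
value by default), LET effects, and the temperature dependence of the
electron thermalization distance (exposed as an optional `sigma_scale` hook,
off by default, because no quantitative parameterization is adopted).
Passing yield tests therefore validate the *relative* temperature and pH
response of the chemistry layer on a literature-standard initial condition,
not absolute track-structure fidelity.

## IRT sampling

For a pair at initial separation r0 with encounter radius a and mutual
diffusion D, the reaction-time CDF is the Smoluchowski first-passage law

    W(t) = (a/r0) · erfc((r0 − a) / √(4 D t)),   W_∞ = a/r0,

inverted with `erfcinv` for one uniform deviate per channel; with
probability 1 − W_∞ the channel never fires.  Background channels draw
exponential deviates at their scavenging capacity (time-homogeneous; no
transient √t correction — consistent with the scavenging-capacity
definition, and listed as a possible extension).

Charged pairs (fully-diffusion-controlled only): both the ultimate
probability and the time law are evaluated in Debye-transformed coordinates,
r → r_eff = rc_s/(exp(rc_s/r) − 1) with rc_s the Onsager radius signed by
the charge product.  Because the packaged rate constants are *observed*
values, the Smoluchowski radius computed from them is already the
Coulomb-inclusive effective radius (k_obs = 4π N_A D r_eff), so only the
separation is transformed.  The exposed `effective_radius` helper implements
the contact→effective map, needed when a channel is specified geometrically
(as in the Brownian-dynamics cross-checks).  Partially-diffusion-controlled
channels (including e_aq + e_aq, whose observed rate is far below the
diffusion limit because of spin statistics) use the plain erfc law with the
Eq.-style radius: their k_obs folds in every interaction and re-dissociation
effect, and no additional Coulomb factor is applied.

Event loop: all initial channels are sampled once; the global minimum fires;
consumed particles cancel their other channels (lazy invalidation on a
heap); products are placed at the √D-weighted midpoint of their parents
(multiple products are separated by half the parent reaction radius, or a
0.29 nm water diameter for background events, along random directions) and
sampled against all survivors and each other — survivor–survivor channels
are *not* resampled, which is the defining IRT approximation.  Ties are
broken by channel creation order, and one PCG64 stream per history makes
timelines bit-reproducible for a fixed seed.

## Step-by-step oracle

The Brownian-dynamics reference propagates ≤ 10 particles with Gaussian
steps (variance 2 D dt per axis), reacting on contact at the same radii the
IRT table uses, with an optional pairwise Euler–Maruyama Debye drift
v = D·rc_s·r̂/r² for charged fixtures.  A guard refuses time steps whose rms
displacement exceeds 0.2× the smallest reaction radius, and a
Brownian-bridge correction — crossing probability
exp(−(r0−R)(r1−R)/(D dt)) between steps — removes the leading
discretization bias of the contact criterion.  The oracle is restricted to
toy fixtures by design; production yields always come from the IRT engine.

## Yields, uncertainties, sweeps

G(t) = 100 · N(t)/E_total is accumulated per run on a 50-point logarithmic
grid (default 10⁻³–10³ μs observation window, simulation truncated at a
configurable end time, default 1 μs, after which counts are frozen).  The
reported uncertainty is the between-run standard error of the mean
(≥ 2 runs required).  Sweeps re-run the full ensemble per condition with
seeds derived from the master seed by a fixed counter scheme, so outputs
are condition-order invariant and reproducible.  The material-balance
percentage is |G_red − G_ox| / mean(G_red, G_ox) × 100 — the symmetric
convention, chosen because the published tables do not state a denominator.

## Validation strategy and problem sizes

The test and acceptance suites run, in increasing scale:

1. closed-form anchors (Onsager radius 0.715 nm, density at 150 °C, pH
   round trips) — exact;
2. sampling-law statistics (first-passage CDF, exponential mean, Einstein
   MSD) at 5×10⁴ draws, 3–3.5 Monte-Carlo σ bands;
3. IRT vs Brownian dynamics on 2- and 3-particle fixtures (neutral and
   charged), 3–4×10³ replicas, 3σ plus explicit truncation/step-bias
   allowances;
4. condition sweeps at 2 runs × 500 spurs per condition (the published
   configuration used 10 runs × 1000 electrons of 10 keV deposited energy;
   the reduced scale trades statistical width for runtime and is reflected
   in the tolerances);
5. the acceptance script uses 2 × 1000 spurs per headline condition.

At these sizes the 25 °C / pH 7 configuration yields G(e_aq)(1 μs) ≈ 2.3
per 100 eV with the packaged spur model, rising with temperature and
dropping at pH 5 in proportion to the H3O⁺ scavenging capacity
(k·[H3O⁺] ≈ 2.1×10⁵ s⁻¹ at pH 5, i.e. ~19% loss by 1 μs) — the published
temperature and pH *responses* are reproduced well within the scaled-down
tolerance, while the absolute normalization inherits the isolated-spur
simplification.

## Known limitations

* Isolated spurs: no track-segment spur overlap, which biases absolute
  yields slightly relative to full track-structure simulations.
* Survivor positions are not resampled at event times when new
  product–survivor channels are formed; this standard IRT shortcut is
  exercised (and bounded) by the 3-particle oracle comparisons.
* No temperature-dependent K_w, no ionic strength, no pressure as an
  independent variable, no homogeneous-stage (beyond-1 μs) chemistry, no
  high-LET mode.
* HO2 is carried for the oxidizing-side bookkeeping but has no producing
  channel in the default low-LET scheme; its G stays 0 unless an override
  adds one.
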