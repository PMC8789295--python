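# Methods

## The biphasic fitness model

One feast–famine cycle is modeled as two sequential exponential growth
phases fed by a finite glucose amount. All bookkeeping is in moles, hours,
µm³ and g/µm³. The phase pieces are closed form:

- glucose-phase cell gain ΔN_g = Y_x/g (1−φ) glc(0) / (ρ V_c,g), with the
  overflow fraction φ ∈ [0,1) the model's single strategy variable;
- glucose-phase duration T_g = ln(ΔN_g/N(0)+1)/μ_g(φ), with
  μ_g(φ) = (1−φ)[α + δ e^{−(β−φ)²/γ²}] in h⁻¹ — zero at φ=1, positive at
  φ=0, peaked at intermediate φ (overflow supports the fastest growth on
  glucose);
- acetate pool ace = Y_a/g φ glc(0); acetate-phase gain
  ΔN_a = Y_x/a ace/(ρ V_c,a) and duration T_a = ln(ΔN_a/N(T_g)+1)/μ_a;
- growth factor G = N_final/N(0) and fitness F = ln(G)/(T_g+T_a), the
  time-averaged growth rate.

Assumptions worth keeping in mind: glucose uptake is entirely
growth-coupled (converting glucose to acetate takes no model time, which is
why φ=1 is a singular point and excluded from the domain); yields and rates
are constants within a phase; and the extra division bonus of oversized
glucose-grown mothers dividing into small acetate-phase daughters is
deliberately not credited to ΔN_a — the closed form stays a lower bound in
that respect, and the size transition appears only in the synthetic-data
generator's volume channel.

Default parameters (overridable individually, via
`ModelParameters.with_overrides` or the YAML config): ρ = 280×10⁻¹⁵ g/µm³,
Y_x/g = 88 g/mol, Y_x/a = 20 g/mol, Y_a/g = 2 mol/mol, V_c,g = 1 µm³,
V_c,a = 0.5 µm³, μ_a = 0.3 h⁻¹, α = 0.2, β = 0.5, γ = 0.4, δ = 2. The
default glucose amount is one average emulsion droplet's content
(2.5 mM × the volume of a 50 µm sphere ≈ 1.64×10⁻¹³ mol) with N(0) = 1, so
default evaluations live in the experimental "5–6 generations per droplet"
regime. Fitness depends on glc(0) and N(0) only through their ratio.

`ode_oracle` re-derives every outcome by forward integration (adaptive RK
with event detection on resource exhaustion, rtol 10⁻¹²) and is used in the
tests as an independent cross-check of the closed form (agreement required
to 10⁻⁵ relative; observed ~10⁻¹³). `optimal_phi` is deterministic: coarse
grid bracketing followed by bounded scalar refinement.

## Cell size–growth rate coupling

Mean cell volume follows V(μ) = V(0) e^{εμ} with V(0) = 0.28 µm³ and
ε = 1.33 h. The coupled model variant substitutes V_c,g = V(μ_g(φ)) and
V_c,a = V(μ_a) per φ; it is opt-in (`couple_volumes` flag /
`coupled_fitness_landscape`) because the reference landscape uses the fixed
1 and 0.5 µm³ volumes. The interior fitness optimum persists under
coupling.

## Droplet and batch propagation

`DropletDesign` derives the Poisson seeding mean λ = cell concentration ×
droplet volume; the defaults (2×10⁶ cells/ml, 50 µm) give λ ≈ 0.131, i.e.
P(exactly one founder) ≈ 0.115 (1 in 8.7 droplets) and P(≥1) ≈ 0.123.

Per transfer the simulator draws Poisson occupancies, assigns founder
genotypes multinomially at current frequencies, grows every droplet to
complete carbon exhaustion (no incubation-time cap), pools, and re-dilutes
to the design concentration — only frequencies carry across transfers.
Droplets are grouped by genotype composition so the cost per transfer is
set by the handful of distinct compositions, not the droplet count.

Multi-founder droplets (6.4% of *seeded* droplets at the default λ) default
to **equal privatized glucose shares** per founder: each founder plays the
biphasic model on glc/k alone. This is the idealization that defines the
emulsion protocol — lineages sharing a droplet do not compete, so expected
frequency change depends only on offspring per founder, and a genotype that
differs only in growth rate is exactly neutral. The alternative
`split="competitive"` races co-seeded lineages for the common pool by
solving the shared-depletion-time equation per phase (Brent root-finding on
Σᵢ nᵢ(e^{μᵢt}−1)/yᵢ = pool); this re-introduces a weak rate selection of
order +0.7% per transfer for a 39%-faster genotype and is the kinetics used
*within* well-mixed batch transfers (`propagate_batch`), where all
genotypes share one glucose pool and the faster grower wins.

Simulated transfers default to 10⁵ droplets (tests use 3×10⁴) rather than
the ~10⁷ a wet emulsion contains; at 10⁵ droplets the per-transfer sampling
drift of a two-genotype frequency is below 0.5%, small against the
yield-selection differential (~2%/transfer for a 23% yield difference).
Mutation is out of scope: the simulator competes predefined genotypes.

## Synthetic growth curves

`generate_timeseries` samples the noise-free closed-form trajectory on a
regular grid (default 5 min for 12 h, 3 replicates) per liter of culture:
2.5 mM glucose, 10⁷ cells/ml inoculum, wild-type φ = 0.25 (an interior
value near the model optimum; the wild-type's absolute overflow ratio is a
modeling choice, exposed in the config). Channels: glucose, acetate
(Y_a/g φ per mol consumed), counts/ml, mean cell volume, and OD = total
biovolume × 10⁻⁹ per ml (the proxy constant cancels in every downstream
ratio). After glucose depletion the mean cell volume relaxes exponentially
from V_c,g toward V_c,a at 1.0 h⁻¹ — fast relative to steady acetate growth
because immediately after the switch oversized mothers divide without
doubling their biomass; the rate is configurable. Measurement noise is
multiplicative lognormal (mean 1, default CV 5%), independent across
channels, time points and replicates.

Strain presets are multiplicative factors on top of the base model. The
evolved-strain preset scales the glucose-phase rate ×1.39, both phase
volumes ×0.89 and the numerical cell yield ×1.23 at unchanged φ; rate,
volume and count yield are independent knobs whose product (1.23 × 0.89 ≈
1.095) is the implied gram-biomass yield change. What the generator does
*not* emulate: lag phases, plate-reader saturation/evaporation artifacts,
autocorrelated sensor drift, droplet-size polydispersity, or any coupling
between noise magnitude and signal level beyond proportionality — so
passing recovery tests demonstrates estimator correctness under the stated
noise model, not robustness to every real-world artifact.

## Growth-curve estimation

- **Maximum specific growth rate**: log-linear least squares in a sliding
  window, maximum slope within the phase. The log signal is first smoothed
  by a 3-point moving average and the default window is 29 points (~2.4 h
  at 5-min sampling, ≈2–3 doublings of the glucose phase), shrinking
  adaptively when a phase holds fewer points (the short acetate phase is
  fit by a single regression). Short windows are deliberately avoided: the
  maximum over many noisy window slopes is an extreme-value statistic, and
  with 9-point windows at 5% noise its upward bias (~+0.15 h⁻¹) is additive
  and therefore distorts *ratios* between strains of different rates. Even
  at 29 points a residual ≈−1 pp bias on the +39% rate contrast remains;
  it is inherent to the max statistic under noise.
- **Diauxic switch**: first sample with glucose below 1% of its initial
  value (threshold chosen to be unreachable by 5% multiplicative noise on
  mid-phase samples).
- **Acetate per glucose**: acetate divided by consumed glucose at the last
  pre-depletion sample. During the glucose phase this ratio equals the
  overflow ratio Y_a/g φ at *every* sample, so the estimate is exact
  noise-free regardless of how the sampling grid falls relative to the
  switch, whereas the raw acetate maximum can land on the falling
  (acetate-consuming) side of the peak for one strain and not another.
- **Yields and volumes**: numerical cell yield = (stationary-mean counts −
  initial counts)/consumed glucose; OD yield analogous. The stationary
  window starts 4 h after the switch (volume settled to <2% of its
  transition span at the default relaxation rate); the exponential-phase
  volume window is t ≤ 0.8 × switch time. The known medium glucose
  concentration can (and in the pipeline does) replace the noisy first
  glucose sample as the consumed-glucose denominator: in a defined medium
  it is a design quantity, and using it removes a single-point 5% error
  from every per-glucose yield. Analyses are per liter, so mol/mol and
  cells/mol quantities need no culture volume.
- **Strain comparison**: per-replicate estimates first, then percent
  difference of strain means (100·(evolved/reference − 1)), replicate
  standard deviation, and a two-sided Welch t-test per metric. With a
  single replicate the p-value is NaN rather than an error.

## Numerical choices and degenerate inputs

φ = 1 raises a domain error naming the singularity; glc(0) = 0 yields
zero-growth outcomes where defined and an undefined-fitness error where
not. Conservation (N_final = N(0)+ΔN_g+ΔN_a) and the exponential
bookkeeping identity hold to 10⁻¹⁰ relative and are asserted in tests.
Landscape grids default to [0, 0.99]. All CSV output uses 17 significant
digits; rerunning any deterministic command byte-reproduces its output, and
every stochastic component draws from a single explicit seed.

## Known limitations

The μ_g(φ) shape is phenomenological — any curve satisfying the three
qualitative constraints (positive at 0, interior peak, zero at 1) would do,
so the *location* of the fitness optimum is not a sharp quantitative
prediction. Acetate toxicity, cross-feeding, oxygen limitation and
mutational input are out of scope. The acetate-phase rate estimate is
weakly determined by design (the phase spans <1 h at 5-min sampling);
its variance is large and it is reported but not emphasized.
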