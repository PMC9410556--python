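# Methods

## Model

Each cell of a one-dimensional filament carries six concentrations: HetR
monomer (R), PatA (A), the combined PatS+PatX inhibitor precursor (S), the
HetN inhibitor precursor (N), the mobile ERGSGR hexapeptide (I), and fixed
nitrogen (G). Fast processes — HetR dimerization, activation of the dimer by
HetF (enhanced by PatA), and inhibition of the active form by the
hexapeptide and by fixed nitrogen — are collapsed into the equilibrium
regulatory function

    g(R, A, I, G) = F_R R^h (1 + A/τ_A)
                    / [1 + F_R R^h (1 + A/τ_A) + I²/K_d² + G/K_G],

with h = 2 by default (HetR binds DNA as a dimer; h = 4 gives the tetramer
variant and leaves every structural property of the model intact). HetF
itself is held at its equilibrium F_eq = β_F/α_F, which enters only through
the lumped constant F_R = F_eq K_F K_R / 2; the nonlinear HetR loss
coefficient μ = (k_b/α_R)(1 − k_u/(k_u + α_d)) likewise summarizes
dimer-mediated degradation. The per-cell dynamics are the six ODEs listed in
the README; S is produced only in vegetative cells, N and G only in
heterocysts. S and N are converted to I at the membrane during export, so
each cell loses S at 2c_S (both faces) while its two neighbours each gain
c_S·S of hexapeptide; I and G additionally hop between neighbours at rates
d_I, d_G. The two terminal cells exchange with one neighbour only and leak I
and G to the medium at the reduced rates d_border·d_I and d_border·d_G.
For a single-cell filament the leak applies on both faces and there is no
conversion influx; this case never arises in practice but is defined for
completeness.

A structural consequence of this bookkeeping is worth stating: because the
outward-facing conversion flux of a terminal cell is lost to the medium even
when d_border = 0, the hexapeptide always has a shallow deficit layer at the
filament ends, of width √(d_I/α_I) cells and relative depth ≈ ½·√(α_I/d_I)
(about 7% at the default parameters). Boundary leakage deepens the wall
value to one half of the bulk. The ends are therefore never perfectly
neutral; leakage is what turns a percent-level bias into the dominant
differentiation site (see Limitations).

## Stochastic integration

The equations are integrated by explicit Euler–Maruyama in the Itô
convention with default dt = 0.01 h. Each species of each cell receives an
independent increment √(Ω_Φ (P + |D|) dt)·ξ, where P and D are that
equation's production and degradation sums — every positively signed term
(basal and regulated production, conversion and transport influx) counts in
P, every negatively signed term (degradation, conversion loss, transport
efflux including boundary leakage) in D. Negative excursions are clipped to
zero after each step; at the default dt the clipping flux is negligible. The
largest rate in the system is the hexapeptide transport (out-rate 2·d_I =
40 h⁻¹), so explicit stepping is stable for dt ≲ 0.025 h; dt = 0.01 leaves a
factor-of-two margin and halving it changes recorded concentrations at
first order only (verified in the suite). Threshold and integral
comparisons in the commitment rule carry a 10⁻⁹ absolute tolerance so that a
target reached exactly on a step boundary is not delayed by float
accumulation.

Cell sizes follow dΛ/dt = λ(1 + ω) with growth-noise amplitude Ω_Λ. Each
cell draws, once at creation, its own maximum size M_Λi ~ N(M_Λ, M_Λ²Ω_Λ)
and its own commitment threshold and integral T_Rj ~ N(T_R, T_R²Ω_Φ),
M_Rj ~ N(M_R, M_R²Ω_Φ); Gaussian draws are clipped below at 10% of their
mean so noise can never produce a non-positive threshold or size. A
vegetative cell reaching M_Λi divides into two half-size cells with
identical concentrations and fresh draws; heterocysts grow to M_Λi, then
stop, and never divide. Commitment progress (∫R dt and the above-threshold
clock) resets to zero in both daughters, since the thresholds it was
accumulating against no longer exist. Within a timestep the order is:
concentration update, commitment update, growth/division; any fixed order
is equivalent to O(dt).

A vegetative cell differentiates when its HetR integral, accumulated only
while R ≥ T_Rj and reset by any dip below, reaches M_Rj — provided at least
T_min = 5 h has elapsed continuously above threshold. With the convention
M_R = 12·T_R (enforced at construction unless explicitly overridden), a cell
held exactly at threshold commits in 12 h, and the minimum-time gate
prevents brief HetR spikes from triggering the extensive morphological
program of a real heterocyst.

Simulations start at the nitrogen step-down: 30 vegetative cells, all
concentrations zero (the deprivation state), sizes uniform on
[M_Λ/2, M_Λ] to avoid the artificial division synchrony a uniform cohort
would produce.

## Parameters

Time is in hours, lengths in μm, concentrations in arbitrary units fixed by
setting the mean commitment threshold T_R = 1. Four constants are pinned to
measured filament biology: M_Λ = 4 μm and λ = 0.08 μm/h (a newborn 2 μm cell
divides after 25 h, giving the observed growth from 30 to roughly 50, 100
and 200 cells at 24, 48 and 72 h), T_min = 5 h, and M_R = 12·T_R (the
longest reported commitment window). The remaining kinetic constants are
calibrated stand-ins obtained with the package's own machinery against the
wild-type and mutant pattern phenotypes: mean vegetative interval ≈ 10 cells
and ≈ 10% heterocysts maintained from 24 to 72 h; no differentiation without
HetF; terminal-only heterocysts with uniformly elevated HetR in the *patA*
background; heterocyst excess ordering ΔpatSΔpatX > ΔpatS > WT. The preset
(shipped as `wild_type_parameters()`):

| group | values |
|---|---|
| production | β_R=0.03, ρ_R=1.2, ρ_A=1.0, ρ_S=4.0, ρ_N=3.0, ρ_G=10.0, β_F=1.0 |
| decay | α_R=0.25, α_A=0.5, α_S=0.2, α_N=0.1, α_I=0.4, α_G=0.7, α_F=1.0, μ=0.5 |
| transport | c_S=0.4, c_N=0.3, d_I=20, d_G=6, d_border=1.0 |
| regulation | F_R=2.0, τ_A=0.7, K_d=0.6, K_G=0.7, h=2 |
| commitment/growth | T_R=1, M_R=12, T_min=5, λ=0.08, M_Λ=4 |
| noise | Ω_Φ=0.05, Ω_Λ=0.10 |

Intuition for the working points: the hexapeptide field equilibrates at
I ≈ 2c_S S/α_I with interaction range √(d_I/α_I) ≈ 7 cells — the scale of
the ten-cell interval. Without PatA the activation term F_R R² alone
balances this inhibition at R* ≈ 0.8, just below threshold, so interior
cells of the *patA* mutant hover under T_R (uniformly elevated relative to
the suppressed bulk of a patterned wild-type filament) and only the
leakage-relieved terminal cells cross it; with PatA the loop gain
(1 + A/τ_A) makes activation bistable enough that cells race past threshold
and the first differentiated heterocysts then suppress their neighbourhoods
through HetN- and G-derived gradients. Growth noise Ω_Λ = 0.10
desynchronizes divisions (division resets commitment progress), which is
what spaces the first simultaneous round of differentiation; genetic noise
Ω_Φ = 0.05 seeds the competition without drowning the deterministic
boundary structure. Mutants are multiplicative overlays on this preset:
production rates zeroed for the hetN/patA knock-outs, β_F (and hence F_R)
zeroed for hetF, and ρ_S reduced to 10% for ΔpatS (the residual patX
redundancy) or to 90% for ΔpatX; overlays compose by multiplication for
double mutants. `DimerKinetics` (k_b=0.125, k_u=0, α_d=1, K_R=2, K_F=2)
reproduces the preset μ and F_R through the reduction formulas.

## Pattern statistics

A filament's pattern is summarized by: vegetative intervals (runs of
vegetative cells bounded by heterocysts on *both* sides — runs touching a
filament end are excluded, matching how between-heterocyst distances are
counted experimentally), heterocyst percentage, contiguous-heterocyst
cluster sizes, terminal-heterocyst counts (the runs touching each end,
summed), and the mean HetR over vegetative cells. Ensembles follow the
replicate convention of 15 batches of 10 filaments: statistics are pooled
within a batch, and the across-batch mean and sample (n−1) standard
deviation play the role of experimental error bars. Distribution
comparisons use the two-sample Kolmogorov–Smirnov distance on the pooled
raw interval samples (scipy's `ks_2samp`), not on binned histograms, to
avoid bin-edge artifacts.

## Calibration

The calibration energy combines, over an "O" group of reference conditions
(wild type and the patS/hetN knock-outs at 24–72 h), the squared KS distance
plus squared errors in mean interval and heterocyst percentage, and over an
"N" group (the patA backgrounds at 24–96 h), the squared KS distance plus a
linear penalty on the simulated heterocyst percentage — the patA backgrounds
pattern almost exclusively at the filament ends, so interior heterocysts are
penalized directly. Default weights are (w1, w2, w3, w4) = (1000, 10, 500,
1). A rescue term (mean vegetative HetR of the wild type minus T_R)²
switches on only when the simulated wild type formed no heterocysts at all,
pushing dead parameter sets back towards patterning; the HetR average is
taken over all recorded snapshots of the wild-type runs. When an interval
sample is empty on one side only, the KS distance is scored as 1 (maximal);
two empty samples agree, and a missing mean counts as zero.

Annealing uses one-parameter multiplicative log-normal proposals
(σ = 0.1 in log space, so parameters stay positive), Metropolis acceptance
exp(−ΔE/T), and geometric cooling by 0.98 every 50 proposals from a
configurable initial temperature; the best-ever parameter set is returned
and proposals with non-finite energy are rejected and counted. The six
constants pinned above (K_d in the spec sense being the measured affinity,
plus λ, M_Λ, T_R, M_R, T_min) are excluded from the default search space.
The objective re-simulates every reference condition with the *same*
per-condition seeds at every proposal (common random numbers), which keeps
the energy landscape smooth enough for the annealer at small replicate
counts. Synthetic reference datasets for self-consistency testing are
generated by the simulator itself (`make-reference --from-simulation`) in a
documented CSV schema (condition, time_h, group, kind, x, value).

Sensitivity of an observable Y to a parameter X is the ratio of relative
changes S_YX = (ΔY/Y)/(ΔX/X), evaluated at X₀ and X₀(1+frac) with
seed-averaged simulations (or a direct evaluator for analytic checks); a
zero baseline leaves S undefined and is reported as NaN.

## Continuum analogy

A two-species reaction–diffusion caricature isolates the boundary
mechanism: a non-diffusing activator r and a diffusing inhibitor s with the
same Hill-type coupling (activator parameters chosen so the homogeneous
state r* ≈ 0.94, s* ≈ 0.74 is stable and not Turing-unstable: the
activator's self-coupling ∂ṙ/∂r < 0 there). With zero-flux boundaries
(∂s/∂x = 0) the homogeneous state persists; replacing them with absorbing
boundaries (s = 0, free leakage) carves an inhibitor gradient falling from
the centre to the ends, and the activator — slaved pointwise to the local
inhibitor level — develops maxima at the boundaries: the continuum picture
of terminal differentiation. Discretization is second-order central
differences (ghost nodes for zero-flux, pinned values for absorbing),
integrated to steady state with LSODA until max|d/dt| < 10⁻⁸. In the
linear test case (constant regulatory activity f₀) the absorbing-boundary
steady state has the closed form
s(x) = (f₀ρ_s/α_s)[1 − cosh(κ(x−L/2))/cosh(κL/2)], κ = √(α_s/d), which the
suite uses to verify both accuracy and the second-order grid convergence.

## What the synthetic data does and does not show

All tests and the acceptance script run on simulator-generated data; no
experimental measurements ship with the package. The generator reproduces
the *statistical structure* of the real system — growth trajectory, interval
distributions, mutant orderings, terminal counts — under the model's own
assumptions. It does not emulate a protoheterocyst intermediate stage (cells
here switch on HetN and fixed-nitrogen production at the instant of
commitment, which under-produces contiguous heterocysts at early times),
cell-morphology effects of *hetF*, nitrogen-history dependence before the
step-down, or measurement noise in microscopy counts. Passing tests
therefore validate internal consistency and the mechanisms' qualitative
phenotypes, not quantitative agreement with any particular experimental
dataset.

## Numerical choices and degenerate inputs

- Explicit Euler–Maruyama at dt = 0.01 h (first-order; the noise term is
  additive per step, so higher-order schemes buy little).
- Concentrations clipped at zero after each step; sizes floored at 10⁻⁹ μm.
- Parameter validation at construction: rates strictly positive except the
  overlay-zeroable ones (β_R, β_F, F_R, μ, ρ_S, ρ_N, ρ_A, ρ_G, d_border ≥ 0);
  Hill order restricted to {2, 4}; the M_R = 12·T_R convention enforced
  unless explicitly overridden.
- Empty filaments, heterocysts passed to the commitment update, negative
  concentrations, unknown config keys and missing parameters all raise
  immediately with the offending name; non-finite states abort a simulation
  with the time, cell index and species of the first bad value.
- Batch seeds derive from numpy's `SeedSequence(base_seed, batch, run)`,
  keeping runs independent without a shared stream; every derived seed is
  reduced below 2³¹.

## Known limitations

- The parameter set is a calibrated stand-in constrained by the printed
  phenotypes, not a fit to interval histograms of any specific experimental
  dataset; quantitative statements (e.g. the ~22% and ~30% vegetative-HetR
  excess of the patA and patA hetN backgrounds over wild type at 48–72 h)
  are properties of this calibration.
- The residual end-bias of the no-leakage model (the conversion-loss
  boundary layer described above) means "no terminal preference without
  leakage" holds as a collapse to near-background rates, not as exact
  rate equality.
- Heterocysts keep evolving R, A, I and G (the equations carry no heterocyst
  gate for them); their HetR regulation is irrelevant to the pattern but the
  values are not meaningful observables.
- No protoheterocyst stage, no hetC/hetP/hetL/patN/hetZ, no ntcA variable
  beyond the fixed-nitrogen inhibition term, no explicit HetF dynamics, and
  no event-driven exact stochastic simulation.
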