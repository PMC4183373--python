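# Methods

## Model

The DNA duplex is reduced to one opening coordinate `y_n` (Å) per base
pair.  The potential energy is

    E = Σ_n V(y_n) + Σ_n W(y_n, y_{n-1}) + V_p(x, {y})

with

* on-site potential `V(y) = D_c (e^{-a_c y} - 1)² + G e^{-(y-b)²/(2w²)}`,
  where the class `c` is A·T or G·C.  The Gaussian term is a solvent
  barrier: it penalizes half-open pairs and stabilizes fully open ones,
  sharpening thermal denaturation;
* stacking `W = (k/2)(1 + ρ e^{-α(y_n+y_{n-1})})(y_n - y_{n-1})²`, whose
  effective stiffness relaxes from `k(1+ρ)` to `k` when either pair opens —
  the source of cooperativity;
* particle coupling `V_p = -A Σ_n f(y_n) e^{-(x-n)²/(2σ²)}` with saturation
  `f(y) = tanh(y/y_sat)` for `y > 0` and `f = 0` otherwise.  `x` is the
  particle coordinate in base-pair index units with periodic wrap; the well
  sum is truncated at `|x-n| ≤ 6σ` (error < 10⁻⁶ A) and wells are not
  wrapped across the periodic boundary — the G·C clamps keep the ends
  closed so the field vanishes there.

Units: energy eV, length Å, mass amu; the derived time unit is
`sqrt(amu·Å²/eV) ≈ 10 fs`.  `k_B = 8.617×10⁻⁵ eV/K`.

### Parameters

| parameter | default | units | why |
|---|---|---|---|
| D_AT / D_GC | 0.05 / 0.075 | eV | standard mesoscopic-DNA Morse depths; G·C stronger |
| a_AT / a_GC | 4.2 / 6.9 | 1/Å | standard Morse inverse widths |
| G, b, w | 0.03, 2.0, 0.5 | eV, Å, Å | solvent barrier between closed and open wells |
| k, ρ, α | 0.025, 2, 0.35 | eV/Å², –, 1/Å | anharmonic stacking |
| A_p | 0.055 | eV | calibrated, see below |
| σ_p | 5 | bp | particle-stabilized bubbles span ~2σ ≈ 10 bp |
| y_sat | 2.5 | Å | coupling saturates at openings of a few Å |
| m / m_p | 300 / 1 | amu / eV·t² | chain pair mass; light particle |
| γ / γ_p | 0.05 / 0.01 | 1/t | thermostat frictions |
| T | 290 | K | simulation temperature |
| clamps | 10 per end | – | G·C pairs held at y = 0 ("hard" boundaries) |

All of these are exposed through `ModelParameters` and the JSON run
configuration, so an alternative parameter set can be dropped in verbatim.

The three coupling constants were calibrated once against the physical
targets the model is meant to meet, not against any test outcome: bound
bubbles should span of order ten base pairs (σ_p = 5 gives 10–14 bp), the
interaction should saturate at typical open-pair displacements of a few Å
(y_sat = 2.5 Å), and A_p must sit in the window where a bubble-plus-particle
state is net favorable on an A/T-rich stretch but not on G·C-rich sequence
(opening n sites costs ≈ n·D_c while the fully-developed well provides
≈ A_p σ_p √(2π) ≈ 0.7 eV; A_p = 0.055 eV makes A/T binding favorable and
G·C binding unfavorable) while leaving the unbound particle mobile (the
background corrugation from thermally jittering pairs stays ≈ 2 k_BT).
Larger A_p produces immobile self-trapped "polarons" on arbitrary sequence;
smaller A_p loses the bubble-stabilization effect.

## Langevin dynamics

Equations of motion: `m ÿ = -∂E/∂y - m γ ẏ + ξ(t)` per free pair and the
analogue for the particle, with white noise of strength `2 m γ k_B T`.  One
step of the fourth-order stochastic Runge–Kutta scheme draws the random
force once, holds it constant across the step (its impulse carries the
exact variance `2 m γ k_B T dt`), and propagates the drift with classical
RK4 stages.  In the deterministic limit the scheme is exactly RK4 (energy
drift O(dt⁴), verified by step-halving); with noise, its stationary error
is O(γ dt), negligible at the operating point γ dt ≤ 5×10⁻³.  A
first-order Euler–Maruyama integrator is included solely as an independent
cross-check of stationary statistics.

Clamped sites are frozen at y = 0; the particle wraps periodically; an
optional reflecting wall `y_wall` confines openings for single-pair
equilibrium studies (the Morse plateau otherwise has infinite measure and
no normalizable Boltzmann density).  Step size dt = 0.05–0.2 time units
(the stiffest mode has ω ≈ 0.15/t, so ω·dt ≤ 0.03).  Each realization
starts from the closed chain with the particle placed uniformly at random,
discards a preheating stretch, and samples every `sample_stride` steps.
Realization streams derive from `SeedSequence(master_seed, realization_id)`
— runs are bit-reproducible and independent of scheduling.

## Analysis pipeline

1. **PCA** of the pooled masked openings.  For promoter scans the
   covariance is mean-centered and trajectories are projected on the first
   `n_pc` components; the particle coordinate is carried alongside and
   never mixed into the covariance.  For the whole-gene, chain-only
   workflow the second moment is taken about the closed state (y = 0): the
   first mode is then the gene's mean breathing profile — delocalized when
   the whole sequence breathes — and localized fluctuation modes follow,
   which is the natural convention for asking *where* a gene is soft.
   Eigenvector localization is quantified by the participation ratio
   `PR = 1/Σ v_n⁴` and by squared-amplitude shares over labeled regions.
2. **Conformational Markov network.**  A microstate is
   (round(x), bin(PC₁), …, bin(PC_k)); bins are equal-width over the pooled
   range of each component.  Nodes are weighted by visit fraction; directed
   edges count frame-to-frame transitions within each realization (never
   across realizations), so the sampling stride is the effective lag time.
3. **Basins.**  Deterministic steepest ascent in occupancy: every node hops
   to its heaviest strictly-heavier linked neighbor (ties broken by lowest
   key) until an attractor is reached.  A stochastic variant (hop
   probability ∝ edge flux) is available behind a seed.
4. **Free energies and dendrogram.**  Node free energies
   `F_i = -ln(P_i/P_max)`; activating microstates in order of increasing F
   grows the basins from their attractors, and the free energy of the ridge
   node that first connects two groups is their barrier.  Merge events form
   the disconnectivity dendrogram (exported as JSON and Newick).
5. **Macrostates.**  Basins whose connecting ridge lies less than
   `barrier_cut` (default 1 k_BT) above the shallower group's bottom are
   clustered.  Basins with occupancy below `ns_threshold` (default 0.005)
   are pooled beforehand into the nonspecific reference `P_NS` — the
   short-lived transitional states in which the particle diffuses between
   targets.  Each macrostate is reported with occupancy `P_α`,
   `ΔF = ln(P_α/P_NS)` (k_BT), entropy `S = -Σ q_b ln q_b` over member
   basins, and its position: the occupancy-weighted modal particle site of
   its member microstates, mapped to genomic labels (+1 at the A of ATG, no
   zero; sequences without an ATG annotation are treated as entirely
   upstream, labels −N…−1).

## Synthetic data

`generate_synthetic_promoter` draws i.i.d. base identities with a
controllable A/T probability and plants A/T-rich windows that stand in for
TSS regions (ground truth returned alongside and written as sidecar JSON).
It emulates the one property the model reads — the A·T/G·C pattern and its
local clustering — and nothing else: no codon structure, no correlated
dinucleotide statistics, no regulatory motifs.  Tests passing on these
sequences demonstrate that the pipeline finds planted soft windows against
a realistic compositional background (A/T 0.4, window 0.95 over 30 bp);
they do not demonstrate TSS prediction on real genomes, which additionally
depends on parameter values this package takes from the literature.

## Problem sizes used by the validation suite

Desk-scale conditions, chosen so the whole suite runs on one CPU core:

* single-pair Boltzmann check: wall at 3 Å, 6×10⁷ steps of dt = 0.1,
  10⁶ retained frames (KS < 0.02 against the quadrature density);
* promoter site recovery: 300 bp + 2×10 clamps, five realizations of
  8×10⁴ time units (4×10⁵ steps of dt = 0.2) per seed, five seeds, with
  n_pc = 3 and n_bins = 6 — at ~4×10⁴ pooled frames a finer grid leaves
  most microstates visited once and fragments the bound state;
* whole-gene mode analysis: 100 bp at A/T 0.9 + 400 bp at A/T 0.35, five
  realizations of 6×10⁴ time units, chain only.

Production scans (the `SimulationConfig` defaults: five realizations of
10⁶ time units, dt = 0.05) sample the landscape far more densely; there the
default n_bins = 10 and n_pc = 5 are appropriate, and macrostate counts
should be checked for stability against n_bins ∈ {6, 10, 15}.

## Numerical choices and degenerate inputs

* Eigenvector signs are fixed (largest-magnitude entry positive) so binning
  is reproducible; degenerate (constant) components get a token bin width.
* PC values at the pooled maximum fall in the last bin; values outside a
  stored range (when re-binning foreign data) are clipped into end bins.
* Exactly tied node weights in basin ascent break toward the lowest key.
* A landscape in which every basin falls below `ns_threshold` is an error
  ("unresolved"), as is an empty FASTA record, a symbol outside A/C/G/T/U,
  or a non-finite state during integration (reported as a dt problem).
* `free_energy_difference` requires strictly positive occupancies; reports
  omit ΔF when P_NS = 0 (no nonspecific states at the chosen threshold).

## Known limitations

* Sequence dependence enters only through the on-site class (A·T vs G·C);
  sequence-dependent stacking, methylation and RNA are out of scope.
* The exact parameter set behind the published *Anabaena* table is not
  public; with literature defaults the pipeline reproduces the method's
  qualitative behavior and the closed-form ΔF relation, not the table's
  occupancy values themselves.
* Desk-scale runs are not fully ergodic: deep bound states can hold a
  realization for its whole duration, so occupancies carry realization
  noise that the production scale averages out.
* Markovianity of the network at the sampling stride is assumed, not
  tested (no implied-timescale analysis); kinetic rates between macrostates
  are not estimated.
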