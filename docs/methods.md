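# Methods

## Model

The package simulates hole transport on an abstract weighted graph of
redox cofactors. A microstate is a 0/1 hole-occupancy vector over the
sites (at most one hole per site); with a fixed total hole count the
state space is all C(n_sites, n_holes) such vectors, enumerated
lexicographically in the landscape's declared site order. The free
energy of a microstate is

    E(S) = Σ_i n_i · e·φ_i + Σ_(a,b) ε_ab · n_a · n_b   [eV]

where φ_i is the site's redox potential (V; a unit hole charge maps V to
eV) and ε_ab are pairwise interaction energies active only under double
occupancy. Hole free energy rises with potential, so holes hop downhill
from high to low potential. In the canonical design the single
interaction term is the 1.6 eV Coulomb repulsion of the bifurcating Trp
dimer: while both dimer holes are present the first hop out of W1 is
driven by an effective 2.7 V (1.1 V intrinsic + 1.6 eV), and after the
first hole departs the remaining hole automatically relaxes to the
intrinsic 1.1 V. This dynamic encoding, rather than a static 2.7 V site,
is what makes the dimer→cold-chain distance matter: with a 5 Å cold edge
the cold hole leaves first (while still repulsion-energized) about 5% of
the time, stranding the partner hole on the relaxed 1.1 V dimer site and
capping the yield near 0.95; at the canonical 10 Å this short-circuit
channel costs only ~1.3 × 10⁻⁴ of the yield.

Transitions move exactly one hole across one declared edge. The
transition-rate matrix uses the column-generator convention — entry
(b, a) is the rate of hop a → b, diagonals are negative column sums — so
dP/dt = K P conserves probability and P(t) = e^{Kt} P(0) holds as
written.

**Terminus trapping.** Cofactors with the `terminus` role are hole
traps: hops out of a terminus are assigned zero rate
(`build_rate_matrix(..., trap_termini=True)`, the default). This encodes
the design intent that the terminal acceptors (e.g. a porphyrin trap on
the hot side, a Tyr–His pair on the cold side) retain their hole for the
duration of one photocycle; re-reduction by sacrificial donors, which
would reset the cycle, is outside the model. The choice is not
cosmetic: with fully reversible termini the 0.05–0.1 eV steps near the
cold trap re-thermalize ~16% of the cold-hole population at 300 K, and
on 10–100 ms time scales the hot hole escapes its 1.6 V trap back to the
vacated 1.1 V dimer site, so no near-unity 1 s yield exists on this
landscape. A reversible variant (`trap_termini=False`) is retained for
sensitivity studies.

## Rate expression

Rates are nonadiabatic (golden-rule) with one classical and one
quantized mode:

    k = (2π/ħ) ⟨V²⟩ (4π λ_out k_B T)^(-1/2)
        Σ_{n=0}^{N} e^{-D} D^n/n! · exp[-(ΔG + λ_out + nħω)² / (4 λ_out k_B T)]

with ⟨V²⟩ = (V₀ e^{-βR})². Defaults (overridable per landscape config):
λ_out = 0.9 eV, ħω = 0.15 eV, D = 0.5 (so λ_in = D·ħω = 0.075 eV),
β = 0.6 Å⁻¹, V₀ = 0.01 eV, T = 300 K, truncation N = 100. The Poisson
weights decay factorially; N = 100 agrees with N = 200 to better than
10⁻¹² relative. Constants are CODATA values in eV units
(k_B = 8.617333 × 10⁻⁵ eV/K, ħ = 6.582120 × 10⁻¹⁶ eV·s). The D → 0
limit is the classical Marcus expression, implemented separately as a
closed-form cross-check. ⟨V²⟩ is taken as exactly the squared
exponential decay — no additional conformational averaging is modeled.

## Numerics

- Propagation uses `scipy.linalg.expm` per requested time; the state
  spaces of interest are small (28 states for the canonical two-hole
  problem) so dense matrix exponentials are exact and cheap even with
  rate-matrix norms of order 10⁹ at t = 1 s. An independent stiff-ODE
  back end (`solve_ivp`, BDF, analytic Jacobian) agrees to 10⁻⁶ per
  component and serves as a consistency check, not the default.
- Completion times are the first crossing of a terminus-occupancy
  threshold, bracketed on a 40-point logarithmic grid over
  [10⁻¹², 1] s and refined by bisection in log time to 0.1% relative.
  The 50% threshold is the reporting convention; with trapped termini
  the curves are monotone so any threshold is well defined.
- The GP Gram matrix gets a 10⁻¹⁰ jitter on the diagonal; observations
  are noiseless (the master-equation objective is deterministic), which
  would otherwise make duplicated design points exactly singular.
  Posterior variances are clipped at zero to absorb jitter-level
  round-off.
- Reporting time grid: 60 points logarithmic in [10⁻⁹, 1] s.

## Bayesian design search

Design coordinates are named landscape overrides
(`potential:<site>` in V, `distance:<a>-<b>` in Å) inside a closed box.
Volts and angstroms are incommensurate, so each coordinate is min–max
scaled to [0, 1] by its bounds before the RBF kernel
k(x, x′) = σ_f² exp(−‖x − x′‖²/2l²); the length scale l = 0.2 is in
scaled units and σ_f² defaults to the variance of the observed yields
(observations are centered so the zero prior mean is unbiased). The
acquisition is the upper confidence bound μ + κσ with κ = 2.0 by
default — a standard exploration/exploitation trade-off, exposed as an
argument. Acquisition maximization uses 2048 seeded uniform candidates
followed by three sweeps of coordinate-wise bounded scalar refinement;
it is deterministic for a fixed seed. The objective is the bifurcation
quantum yield at t = 1 s. Hyperparameter refitting by marginal
likelihood was deliberately omitted: the search spaces of interest are
low-dimensional boxes around a known basin, where the fixed-l surrogate
already rediscovers ≥ 0.99-yield designs within 50 evaluations.

## Synthetic landscapes

`random_landscape` keeps a template's topology and redraws every relay
and terminus potential uniformly within given bounds and every edge
distance uniformly within bounds — the same box-bounded uniform
distribution the optimizer searches, which is exactly what its initial
data should look like. Bifurcation-site potentials stay at the template
value (they are fixed by the dimer chemistry, not by placement).
`perturbed_fig8` adds uniform jitter to the canonical design to map its
high-yield basin; ±0.02 V on the relay/terminus potentials keeps the
1 s yield above 0.9. What the generator does **not** emulate: correlated
potential fluctuations from protein conformational dynamics, distance
fluctuations on the hopping time scale, or any coupling between
potentials and distances — passing tests demonstrate the solver and
optimizer are correct on the model class, not that a real protein will
realize a given landscape.

## Trp-pair analysis

The repulsion module treats quantum-chemistry outputs as inputs: the
interaction energy of the doubly oxidized dimer is the difference of one
residue's HOMO energy with its partner charged versus neutral, and the
packaged 11-snapshot table (MD-sampled conformations) averages to
1.6339 eV, rounded to the 1.6 eV used in the kinetic landscape.

Geometry statistics of a Trp pair from PDB coordinates: closest H–H
distance (minimum over inter-residue hydrogen pairs); inter-plane angle
between least-squares (SVD) planes of the nine indole ring atoms, folded
to [0°, 90°]; and ring overlap area, computed by projecting both rings
onto the least-squares plane of the *first* ring (the stated
convention — no symmetric average) and intersecting the convex hulls of
the projected atoms. Indole is convex to good approximation, so the
hull sidesteps outline-ordering ambiguity; the projection-plane and
hull conventions are documented here because other choices (mean plane
of both rings, exact bicyclic outline) would shift areas by a few
percent.

## Validation conventions

The hop graph must be connected, where sites linked by an interaction
term count as connected: the bifurcating dimer is one physical module
even though no intra-dimer hop edge exists (the two holes never exchange
sites; each is routed to its own pathway). Config files use
unit-suffixed keys (`potential_V`, `distance_A`, `epsilon_eV`,
`temperature_K`) so that unit-less documents fail with a named field.

## Known limitations

- The kinetic model is a closed system for one photocycle: no hole
  refilling by sacrificial donors, no steady-state flux balance, no
  deprotonation channel for the Trp radical cations (slower than the
  simulated window), and no cross-pathway short-circuit edges in the
  canonical topology (the schema permits adding them).
- The design's nominal pathway-completion scales are order 10⁻⁵ s (hot)
  and 10⁻² s (cold). The 50%-crossing times computed here from the rate
  expression and the stated parameters are faster — 2.6 × 10⁻⁷ s and
  6.2 × 10⁻⁴ s — while preserving the ~3-decade hot/cold separation and
  the strict hot-before-cold ordering at every threshold. Completion
  estimates read off saturating curves depend strongly on the threshold
  convention (a 99.9% criterion roughly accounts for the cold-side gap
  but not the hot-side one) and, through the exponential activation
  factor, on λ_out and the potential steps; the order-of-magnitude
  *ratio* of the two time scales is the robust prediction, the absolute
  values are not.
- Potentials are relative to the design's internal 1.0 V cold-terminus
  reference; no absolute electrochemical scale is implied.
- The Trp-pair statistics require hydrogens in the input coordinates;
  no hydrogen placement is performed.
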