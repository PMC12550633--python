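# holebif

Kinetic simulation and Bayesian design of **light-driven hole bifurcation
(HB)** in de novo redox proteins.

Hole bifurcation is the splitting of a pair of oxidizing equivalents
("holes") from a single site onto two spatially separated transport
pathways poised at different electrochemical potentials. The design
studied here places two nearby tryptophan residues (a Trp dimer) at the
bifurcation site: after a flash-quench event doubly oxidizes the dimer,
the ~1.6 eV electrostatic repulsion between the two Trp radical cations
energizes the first departing ("hot") hole to an effective potential of
2.7 V, while the second ("cold") hole relaxes to the intrinsic 1.1 V once
its partner leaves. A short 5 Å chain of high-potential cofactors carries
the hot hole to a 1.6 V trap, and a chain starting with a deliberately
longer 10 Å hop carries the cold hole to a 1.0 V trap, yielding 1:1
partitioning of the two holes.

`holebif` provides, for users modeling multistep electron/hole transport
in engineered proteins:

- a **landscape** data model (cofactor potentials, hop edges with
  edge-to-edge distances, pairwise hole–hole interaction terms) with a
  validated YAML config format;
- **microstate master-equation kinetics**: occupancy vectors
  S = [n₁, …, n_N], a transition-rate matrix K with
  k_ii = −Σ_{j≠i} k_ji, and P(t) = e^{Kt} P(0);
- **nonadiabatic rates** in the Marcus–Jortner form with one quantized
  mode,

  k_{i→j} = (2π/ħ) ⟨V_ij²⟩ (4π λ k_B T)^{-1/2}
  Σ_n (e^{-D} D^n / n!) exp[−(ΔG_ij + λ + nħω)² / (4 λ k_B T)],

  with ⟨V_ij²⟩ = (V₀ e^{−β R_ij})², λ = 0.9 eV, ħω = 0.15 eV,
  Huang–Rhys factor D = 0.5, β = 0.6 Å⁻¹, V₀ = 0.01 eV, T = 300 K;
- **observables**: the bifurcation quantum yield (probability of the
  microstate with exactly one hole on each pathway terminus), per-terminus
  arrival curves, and threshold completion times;
- a from-scratch **Gaussian-process / UCB Bayesian optimizer** (RBF
  kernel, noiseless posterior, acquisition α(x) = μ(x) + κσ(x)) that
  searches cofactor potentials and distances for high-yield designs;
- **Trp-pair analysis**: the repulsion-energy bookkeeping
  (E_int = E_HOMO(charged partner) − E_HOMO(neutral partner), with the
  packaged 11-snapshot table averaging 1.6339 eV) and geometry statistics
  (closest H–H contact, indole inter-plane angle, projected ring overlap
  area) from PDB coordinates.

## Worked example

```python
from holebif import fig8_landscape, quantum_yield, completion_time

L = fig8_landscape()          # the canonical optimized 8-site design
y = quantum_yield(L, t_final=1.0)
th = completion_time(L, "hot", 0.5)
tc = completion_time(L, "cold", 0.5)
print(f"bifurcation quantum yield at 1 s : {y:.6f}")
print(f"hot terminus 50% crossing        : {th:.3e} s")
print(f"cold terminus 50% crossing       : {tc:.3e} s")
```

prints

```
bifurcation quantum yield at 1 s : 0.999701
hot terminus 50% crossing        : 2.582e-07 s
cold terminus 50% crossing       : 6.238e-04 s
```

i.e. starting from the doubly oxidized Trp dimer, 99.97% of the
probability ends on the target microstate (one hole on each terminus)
after 1 s, and hot-hole transport completes roughly three orders of
magnitude faster than cold-hole transport — the kinetic signature of the
repulsion-driven, distance-biased design.

The same simulation from the shell:

```bash
holebif fixtures --out work/            # write the canonical config
holebif simulate work/canonical_landscape.yaml --out work/sim
holebif yield work/canonical_landscape.yaml
```

`simulate` writes the full 28-state trajectory CSV, the hot/cold arrival
curves (CSV + figure) and a JSON summary. `holebif optimize` runs the
GP/UCB search over a JSON box of tunables, and `holebif geometry` emits
per-snapshot Trp-pair statistics from a PDB file.

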