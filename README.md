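# condrheo

Coarse-grained simulation and rheology of aging biomolecular condensates.

Biomolecular condensates — dense droplets formed by phase-separating
proteins — start life liquid-like and age toward solid-like states, a
transition implicated in neurodegenerative disease. Three molecular drivers
of that maturation are solvent expulsion (desolvation), backbone
rigidification (e.g. β-strand formation), and the lifetime of "sticker"
contacts between chains. `condrheo` packages the models and measurements
needed to dissect these drivers at desk scale:

* **Models** — sticker-spacer bead-spring chains (FENE bonds, k = 30 ε/σ²,
  R₀ = 1.5σ; harmonic angles for stiffness; LJ pair interactions with
  repulsive 2^{1/6}σ or attractive 4σ cutoffs) with explicit solvent, plus
  a residue-level hydropathy-scaled (Ashbaugh–Hatch λ-LJ) model built from
  a FASTA sequence and a per-residue parameter CSV. All in reduced LJ units.
* **Engine** — numba-accelerated BAOAB Langevin dynamics with cell-list
  neighbor search, kinetic+virial stress, reflective walls, and oscillatory
  Lees–Edwards shear with the thermostat on peculiar velocities.
* **Rheology** — the equilibrium Green-Kubo route
  G*(t) = V/(5kBT)[ΣC_offdiag + (1/6)ΣC_ndiff] with a multi-tau correlator,
  generalized-Maxwell fits G(t) = G₀ + Σ Gᵢe^{−t/τᵢ}, zero-shear viscosity
  η* = Σ Gᵢτᵢ, G′/G″ spectra, crossovers, and Maxwell-fluid vs
  Kelvin-Voigt-solid classification; plus the direct oscillatory-shear
  route Σxy = Σ₀ sin(ωt+δ) → G′ = Σ₀cos δ/γ₀, G″ = Σ₀sin δ/γ₀.
* **Structure** — persistence length (tangent correlations and
  ℓp = −1/ln cos θm), radius of gyration, subdiffusion exponents, density
  profiles.
* **Phase diagram** — slab coexistence by tanh interface fits and
  critical-point extrapolation via rectilinear diameters with β = 0.325.
* **Aging** — nonequilibrium solvent evaporation at a walled boundary with
  a following wall, producing the corona shell: a dense polymer crust that
  traps interior solvent.

## Worked example

```
$ python examples/melt_rheology.py
built melt: 500 beads, box edge 8.38 sigma

G*(0) = 66.4 p*  (instantaneous modulus)
Maxwell modes of the long-time branch (G_i in p*, tau_i in tau):
  G =   2.010   tau =     4.30
  G =   0.198   tau =   311.27
zero-shear viscosity eta* = sum G_i tau_i = 70.41 p*.tau
terminal log-log slopes: G' ~ w^2.00, G'' ~ w^1.00
  (a Maxwell fluid approaches G' ~ w^2 and G'' ~ w as w -> 0)
G' = G'' crossover at w = 0.00453 rad/tau (loss-dominated below, storage above)
G' = G'' crossover at w = 0.0211 rad/tau (storage-dominated below, loss above)
G' = G'' crossover at w = 0.186 rad/tau (loss-dominated below, storage above)
```

A dense semiflexible melt (ℓp ≈ 5σ) relaxes as a Maxwell fluid: a fast
segmental mode and a slow chain mode, terminal G′ ∼ ω² and G″ ∼ ω, a
finite zero-shear viscosity, and an interior storage-dominated window
between the two relaxations where the chain stiffness stores elastic
energy. The other scripts in `examples/` each exercise one capability —
oscillatory shear, gel vs melt classification, the phase diagram, corona
formation during aging, chain structure, and the residue-level model. A
thin CLI (`condrheo build|simulate|rheology|workflow ...`) wraps the same
library calls for shell use; `condrheo.workflows.run_workflow` orchestrates
the named end-to-end studies (solvent_sweep, rigidity_sweep,
length_compare, gel_vs_melt, sticker_sweep, aging, phase_diagram), each
with a `reduced` desk-scale preset and a checksummed run manifest.

## Layout

```
src/condrheo/     library (builders, engine, rheology, observables,
                  phase, aging, hps, workflows, io, config, cli)
examples/         narrative scripts, one per capability
tests/            pytest suite (closed-form oracles, property tests,
                  reduced-scale end-to-end checks)
docs/methods.md   models, estimators, numerical choices, limitations
```
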