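# Methods

`condrheo` simulates coarse-grained models of biomolecular condensates and
measures their viscoelasticity, phase behavior and nonequilibrium aging.
Everything runs in reduced Lennard-Jones units: bead mass m, diameter σ and
well depth ε set the scales, so time is τ = √(mσ²/ε), temperature ε/kB,
density σ⁻³ and stress/modulus p* = εσ⁻³ (kB = 1).

## Models

**Sticker-spacer bead-spring chains.** Backbone beads are connected by FENE
springs, U = −½kR₀²ln(1−r²/R₀²), with k = 30 ε/σ² and R₀ = 1.5σ, on top of a
Lennard-Jones pair interaction. The nonbonded interaction is either purely
repulsive (cutoff 2^{1/6}σ, the athermal melt used for rheology) or
attractive with cutoff 4σ (phase-separation and sticker channels). The
plainly truncated potential is energy-shifted at the cutoff so the
bookkeeping energy is continuous (forces unchanged); a shifted-force
variant additionally brings the force continuously to zero at the cutoff
and is used for attractive rheology runs. Backbone stiffness comes from a
harmonic angle term U = K(θ−θ₀)²; K = 10 (in kBT) with θ₀ between 111.6°
(fully flexible limit, ℓp ≈ σ) and ~170° (rod-like, ℓp ≳ 15σ) spans the
rigidity range studied. Stickers are placed every n-th bead (ten by
default), interact through their own attractive channel of depth χps, and
consecutive sticker triplets carry a stiff angle at ~180° (straight,
β-strand-like segments). Long-lived sticker pairs are modelled as
irreversible harmonic cross-links (U = k(r−r₀)², k = 300 ε/σ², r₀ = σ);
transient pairs as the attractive χps channel. Solvent is a free repulsive
monomer species.

**Residue-level chains.** One bead per residue, harmonic bonds (3.8 Å),
and the Ashbaugh–Hatch hydropathy-scaled pair form: inside the LJ minimum
the full repulsion acts with the well lifted by (1−λ)ε; outside, the
attraction is scaled by λ, the arithmetic mean of the two residues'
hydropathy weights. A declared (length, energy, mass) scale — 6.5 Å, one ε,
110 Da by default — converts a user-supplied per-residue CSV table into
reduced units so the same integrator drives both models; bonded first
neighbors are excluded from the nonbonded sum (the 3.8 Å bond sits deep
inside the repulsive core), and production runs use a smaller time step
(0.002 τ) because the smallest residue beads make the pair forces stiffer
in reduced units. Electrostatics
are deliberately omitted: this is the module's defining approximation, so
sequence-charge effects are out of scope and only hydropathy-driven,
qualitative behavior should be read from it. Explicit solvent couples to
residues through a small effective λ; with λ = 0 the solvent demixes from
the protein, so a minimal attraction (default 0.2) keeps the condensate
homogeneously solvated.

## Dynamics

A BAOAB-split Langevin integrator (friction γ = 1 τ⁻¹ by default, a
choice the model literature leaves open; time step 0.005 τ, within the
0.005–0.01 τ range appropriate for these force fields) samples the NVT
ensemble. With γ = 0 the scheme reduces to velocity-Verlet; the test suite
pins energy conservation there (secular drift < 10⁻⁴ relative over 10⁴
steps — the bounded shadow-Hamiltonian oscillation, ~3·10⁻⁴ at this time
step, is not drift). Pair interactions use a cell list with a 0.3σ Verlet
skin rebuilt on a displacement criterion; its equivalence to a brute-force
O(N²) loop is asserted in tests. Runs are chunked with per-chunk seeds
derived from the user seed, so every trajectory is bit-reproducible.

**Oscillatory shear.** Instead of full SLLOD, the box is deformed
triclinically: each step applies the affine map x → x + dγ·y, the xy tilt
follows γ(t)·Ly with Lees–Edwards remapping (a particle crossing the y
boundary is shifted by the tilt and by the image streaming velocity), and
the thermostat acts on peculiar velocities (streaming profile u_x = γ̇y
removed). In the linear-response regime this produces the same moduli as
SLLOD; the package does not assume that equivalence but asserts it through
the Green-Kubo/oscillatory-shear agreement test. The strain resolution
guard rejects ω·dt > 0.1 rad/step.

**Stress.** The kinetic + pairwise-virial estimator. Diagonals follow the
pressure-tensor sign (ideal gas: Σxx = ρkBT > 0); off-diagonals are
recorded with the material (tension-positive) sign so that shearing an
elastic solid by +γ yields +Gγ. Autocorrelations and normal-stress
differences are independent of either choice.

## Rheology

**Green-Kubo.** The relaxation modulus is the isotropic average

    G*(t) = V/(5 kB T) [ C_xy + C_xz + C_yz + (1/6)(C_Nxy + C_Nxz + C_Nyz) ],

with C the autocorrelations of the off-diagonal stresses and of the
normal-stress differences N_ij = Σii − Σjj. For an isotropic system each
normal-difference autocorrelation equals four times an off-diagonal one,
collapsing the estimator to V/(kBT)⟨Σxy(0)Σxy(t)⟩ — the identity that
fixes the 1/6 weight (it is still exposed as `ndiff_weight`). Off-diagonal
channels are correlated as raw products, without mean subtraction: a
fluid's sample mean contributes an offset far below the noise floor, while
a cross-linked network's frozen residual shear stress is precisely what
carries the equilibrium plateau of G*(t) — subtracting it would erase the
gel signal. The normal-difference channels do have their sample mean
removed (they carry a genuine anisotropy offset in finite samples).
Autocorrelations use a multi-tau correlator (16 lags per level, block
factor 2): each level block-averages the previous one, so long lags come
almost noise-free at logarithmic spacing.

**Maxwell analysis.** G*(t) of these melts has two branches: a short-time
vibrational branch (bond/cage ringing, decaying within ~0.3 τ and not
representable by a few positive exponentials) and a configurational
long-time branch. Maxwell modes G(t) = Σ Gᵢ e^{−t/τᵢ} are fitted to the
long-time branch (default split t = 0.5 τ, exposed as `gk_t_min`); the
fit is a bounded nonlinear least squares in log-parameters, initialized by
non-negative least squares on a dense log-spaced τ grid, with relaxation
times confined to the data window so no mode can escape below the shortest
lag with an unconstrained amplitude. Data beyond the first zero crossing
of the fluid branch is treated as noise and sets the weighting floor. The
mode count grows until the residual stops improving by 5%. A gel is
detected when G*(t) levels off above 5% of G*(0); the fit then includes an
equilibrium plateau G₀ and the zero-shear viscosity is infinite. The fast
branch optionally gets one effective mode (fitted to its positive excess
over the slow branch) so full-band spectra include the high-frequency
viscous loss; terminal quantities always use the slow branch alone.

Spectra come from the fitted modes analytically, G′ = Σ Gᵢω²τᵢ²/(1+ω²τᵢ²)
and G″ = Σ Gᵢωτᵢ/(1+ω²τᵢ²) (+G₀ on G′), rather than from a numerical
Fourier transform of noisy data. An exact Filon-type transform of the
piecewise-linear G*(t) interpolant (`modulus_from_relaxation`) is available
as the noise-tolerant route at mid/high frequencies, optionally smoothed
over a ~25% frequency neighborhood; it is the comparison arm of the
Green-Kubo vs oscillatory-shear consistency test.

**Terminal slopes.** The "lowest reliable decade" for terminal power laws
is evaluated on the fitted model over ω ∈ [0.01, 0.1]/τ_max — one to two
decades below the slowest fitted relaxation rate, i.e. the terminal regime
the fit actually resolves, mirroring how ω → 0 asymptotics are quoted from
Maxwell fits in practice.

**Oscillatory analysis.** The stress record is decomposed by least squares
into in-phase and quadrature parts relative to the strain's own fitted
phase (so a non-integer cycle count cannot bias the split); the first
cycle is discarded. Because thermal stress noise rides on the sinusoid,
the quality gate is the standard error of the fitted amplitude relative
to the amplitude (limit 50%), not the raw residual. The linear-regime
check sweeps γ₀ and accepts amplitudes whose moduli stay within 10% of
the smallest-amplitude reference.

**Classification.** Over the lowest sampled frequency decade: G′ slope ≈ 2
with dominant G″ → Maxwell fluid; flat dominant G′ plateau → Kelvin-Voigt
solid; G″ > G′ everywhere with no elastic window → viscous fluid;
otherwise indeterminate. Crossovers G′ = G″ are located by log-log linear
interpolation between grid points.

## Chain observables

Persistence length comes two ways: (i) tangent-tangent correlations along
the contour fitted to exp(−Δs·b/ℓp) down to 1/e² (anchored at Δs = 0;
non-decaying correlations flag a rod-like lower bound), and (ii) the
equilibrium-angle formula ℓp = −1/ln(cos θm) with θm = 180° − θ_interior,
the bond-deflection angle — the convention under which the flexible limit
θ₀ = 111.6° gives ℓp ≈ 1 bond length. Rg uses unwrapped coordinates
(builders seed periodic image flags by walking each chain through
minimum-image bonds, so chains are whole from frame zero). MSD is
multi-origin on a log-spaced lag grid; the subdiffusion exponent is the
log-log slope over a window between the bead friction time (γ⁻¹ = 1 τ)
and a tenth of the slowest Maxwell relaxation time — the intermediate
regime between free-monomer and whole-chain motion. Both monomer and
chain-centroid MSD are available (which one a given observation refers to
is often ambiguous; the monomer version is the default).

## Phase diagram

Slab profiles are recentered by a density-weighted circular mean (so the
dense phase never straddles the periodic seam), time-averaged, and fitted
to a two-interface tanh form; the plateaus give ρl and ρv, and a profile
without two-phase contrast returns a supercritical flag. The critical
point is a simultaneous least-squares fit of the rectilinear-diameter law
(ρl+ρv)/2 = ρc + A(Tc−T) and the order-parameter scaling
ρl−ρv = Δρ₀(1−T/Tc)^β with β fixed at 0.325 (overridable). The fit is
exercised both on synthetic coexistence curves (exact recovery) and on
simulated slabs in the phase-diagram workflow.

## Aging protocol

Geometry: cuboid box elongated in x, reflective walls on x, periodic y/z.
Every control interval (1 τ) the integrator advances, then solvent beads
whose x lies within `boundary_slab` of the +x wall evaporate, closest to
the wall first, under a cumulative quota of `evap_rate` beads per τ (10/τ
by default). The printed slab thickness of 10⁻²σ is thinner than a bead
diameter and essentially never contains a bead center; the practical
default is 0.5σ, with the literal value available as a plain parameter.
The wall then advances: `wall_follow` mode is a proportional controller
that tracks the initial kinetic pressure of a 1σ control slab at the wall
(a barostat-free stand-in for "the box shrinks as solvent leaves"), capped
at `shrink_speed` and halting with a flag before crossing the polymer
extent; a constant-speed mode exists for controlled tests. Polymer is
never removed, so the bookkeeping is exact: solvent count decreases by
exactly the number of evaporation events. An optional rigidity schedule
ramps the angular stiffness linearly over the run, emulating progressive
chain rigidification.

Corona metrics reduce the (time × bin) density record to one dimension:
the shell is the outermost contiguous run of bins with ρpoly above a
threshold (0.5 σ⁻³ ≈ 2× the bulk polymer density in the default mixtures);
onset is the first recorded time its width reaches two bins; trapped
solvent is the final interior solvent population relative to the initial
load. Two-dimensional boundary-plane porosity is not modelled.

## Synthetic study systems and what they do (not) show

The generator defaults are the study conditions: polymer:solvent ratios
1:2, 1:1, 2:1, 1:0; chain lengths 20 and 200 (full scale) with 40 as the
reduced long-chain stand-in; melt density 0.85 σ⁻³; T = 1; stiffness
θ₀ = 150°, K = 10 giving ℓp ≈ 5σ as the fixed reference rigidity; stickers
every ten beads. Chains are grown as directionally-correlated random walks
(bond 0.97σ, deflections drawn near the equilibrium angle) and relaxed by
a ramped soft cosine push-off until no nonbonded pair is closer than 0.8σ
— FENE springs cannot tolerate hard-core overlaps. Builders are pure
functions of (composition, blueprint, seed).

Desk-scale tests run ~10³-bead systems for 10²–10³ τ. They resolve
terminal Maxwell scaling, subdiffusion, the rigidity-dependence of the
elastic window, gel plateaus and corona formation — but not the absolute
moduli or crossover frequencies of 200-bead-chain, ω ~ 10⁻⁶ systems,
which require cluster-scale runs of the same code paths (the workflows'
non-reduced presets). In particular, at Np = 20 even stiff chains show no
interior elastic window (too few entanglements) — reproducing, at reduced
scale, the observation that short chains lose the elastic-dominated
regime; the window test therefore uses Np = 40 with near-rod stiffness.
The residue-level model at desk scale shows qualitative orderings only.

## Numerical choices and limitations

* Mode merging: fitted relaxation times closer than 10% are merged
  (amplitude-weighted) so τᵢ stay strictly ordered.
* Crossover ties (tangency) are reported as zero-width crossings.
* Minimum-image under tilt uses the sequential wrap (z, then y adjusting x
  by the tilt, then x): exact whenever the true separation is below half
  the smallest box dimension, i.e. everywhere forces are evaluated.
* The evaporation thermostat absorbs the momentum/energy carried away by
  removed beads; no explicit bookkeeping correction is applied.
* No entanglement (primitive-path) analysis, no barostats, no long-range
  electrostatics, no bead-tracking microrheology.
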