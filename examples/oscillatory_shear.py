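"""Oscillatory shear of a melt: storage and loss moduli at one frequency.

Applies a sinusoidal Lees-Edwards strain gamma_xy = 0.1 sin(0.5 t) to a
small flexible melt and decomposes the stress response into in-phase
(elastic, G') and quadrature (viscous, G'') parts.

Run:  python examples/oscillatory_shear.py       (~1 minute)
"""

from condrheo.builders import Composition, build_melt, default_forcefield
from condrheo.engine import ShearProtocol, oscillatory_shear_run, run_nvt
from condrheo.rheology import os_moduli_from_run

comp = Composition(n_chains=25, chain_length=20, target_density=0.85, seed=5)
system, topology = build_melt(comp)
ff = default_forcefield()
run_nvt(system, topology, ff, n_steps=10_000, dt=0.005, temp=1.0, seed=6)

protocol = ShearProtocol(gamma0=0.1, omega=0.5, dt=0.005, n_cycles=12)
_, raw = oscillatory_shear_run(system, topology, ff, protocol, seed=7, sample_stride=4)
pt = os_moduli_from_run(raw, protocol.omega)

print(f"omega = {pt.omega} rad/tau, gamma0 = {protocol.gamma0}")
print(f"G'  (storage) = {pt.g_storage:.3f} p*")
print(f"G'' (loss)    = {pt.g_loss:.3f} p*")
print(f"stress amplitude Sigma0 = {pt.sigma0:.4f} p*, phase lag delta = {pt.delta:.3f} rad")
print("delta between 0 (elastic solid) and pi/2 (Newtonian fluid); "
      "G'' > G' marks a viscous-dominated response at this frequency.")
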