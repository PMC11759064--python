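"""Reduced Lennard-Jones units.

All engine quantities are expressed in reduced units built from the bead
mass ``m``, diameter ``sigma`` and well depth ``epsilon``:

* time        ``tau = sqrt(m sigma^2 / epsilon)``
* density     ``rho = sigma^-3``
* temperature ``T = epsilon / kB``
* pressure    ``p = epsilon sigma^-3``

Boltzmann's constant is 1 in these units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

KB: float = 1.0


@dataclass(frozen=True)
class ReducedUnits:
    """Derived reference units for a given (m, sigma, epsilon) triple."""

    mass: float = 1.0
    sigma: float = 1.0
    epsilon: float = 1.0

    @property
    def tau(self) -> float:
        return math.sqrt(self.mass * self.sigma**2 / self.epsilon)

    @property
    def rho(self) -> float:
        return self.sigma**-3

    @property
    def temperature(self) -> float:
        return self.epsilon / KB

    @property
    def pressure(self) -> float:
        return self.epsilon * self.sigma**-3
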