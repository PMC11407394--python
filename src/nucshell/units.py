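"""Reduced simulation units.

All geometry in the package is expressed in the bead diameter ``sigma``, all
energies in the thermal energy ``kT`` (1 kT is roughly 0.6 kcal/mol at room
temperature) and all times in the intrinsic unit ``tau``. One chromatin bead
corresponds to 40 kb of chromatin at the default genomic resolution.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class SimulationUnits:
    """Unit system of a simulation: length ``sigma``, time ``tau``, energy ``kT``.

    Every quantity the package emits is denominated in these units; the class
    only carries the conversion factors a user needs to map results onto
    physical scales (e.g. sigma in nanometres).
    """

    sigma: float = 1.0
    tau: float = 1.0
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.tau <= 0 or self.kT <= 0:
            raise ValueError("sigma, tau and kT must all be strictly positive")


#: genomic resolution of one chromatin bead
KB_PER_BEAD = 40.0
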