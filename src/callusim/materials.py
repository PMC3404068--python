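"""Tissue phenotypes and their biphasic material properties.

Properties follow the standard poroelastic fracture-healing material set:
Young's modulus in MPa, permeability in mm^2, fluid dynamic viscosity in
N s/mm^2, porosity dimensionless.  The working unit system is mm-N-s-MPa,
in which the Darcy mobility k/mu of granulation tissue
(1e-11 mm^2 / 1e-9 N s/mm^2 = 1e-2 mm^4/(N s)) matches the classic
poroelastic callus models.  Calcified cartilage is cartilage stiffened by a
factor of two (E = 20 MPa), all other properties identical to cartilage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = ["Phenotype", "MaterialTable", "BONE_PHENOTYPES", "PHENOTYPE_CODES"]


class Phenotype(IntEnum):
    """Tissue phenotype of a mesh element."""

    GRANULATION = 0
    FIBROUS = 1
    CARTILAGE = 2
    CALCIFIED_CARTILAGE = 3
    MARROW = 4
    IMMATURE_BONE = 5
    MATURE_BONE = 6
    CORTICAL_BONE = 7


#: phenotypes that act as a stiff (bony) substrate for osteogenesis
BONE_PHENOTYPES = frozenset(
    {Phenotype.IMMATURE_BONE, Phenotype.MATURE_BONE, Phenotype.CORTICAL_BONE}
)

#: integer code table used in VTK/CSV output
PHENOTYPE_CODES = {p.name.lower(): int(p) for p in Phenotype}

_N_PHEN = len(Phenotype)


def _prop_array(values: dict) -> np.ndarray:
    arr = np.empty(_N_PHEN)
    for p in Phenotype:
        arr[int(p)] = values[p]
    return arr


@dataclass
class MaterialTable:
    """Per-phenotype biphasic properties, indexable by :class:`Phenotype`.

    Each field is an array of length ``len(Phenotype)``; ``table.young[p]``
    etc.  Defaults are the standard fracture-callus property set; the
    calcified-cartilage modulus is tied to twice the cartilage modulus.
    """

    young: np.ndarray = field(
        default_factory=lambda: _prop_array(
            {
                Phenotype.GRANULATION: 0.2,
                Phenotype.FIBROUS: 2.0,
                Phenotype.CARTILAGE: 10.0,
                Phenotype.CALCIFIED_CARTILAGE: 20.0,
                Phenotype.MARROW: 2.0,
                Phenotype.IMMATURE_BONE: 1000.0,
                Phenotype.MATURE_BONE: 6000.0,
                Phenotype.CORTICAL_BONE: 20000.0,
            }
        )
    )
    permeability: np.ndarray = field(
        default_factory=lambda: _prop_array(
            {
                Phenotype.GRANULATION: 1e-11,
                Phenotype.FIBROUS: 1e-11,
                Phenotype.CARTILAGE: 5e-15,
                Phenotype.CALCIFIED_CARTILAGE: 5e-15,
                Phenotype.MARROW: 1e-14,
                Phenotype.IMMATURE_BONE: 1e-13,
                Phenotype.MATURE_BONE: 3.7e-13,
                Phenotype.CORTICAL_BONE: 1e-17,
            }
        )
    )
    poisson: np.ndarray = field(
        default_factory=lambda: _prop_array(
            {
                Phenotype.GRANULATION: 0.167,
                Phenotype.FIBROUS: 0.167,
                Phenotype.CARTILAGE: 0.167,
                Phenotype.CALCIFIED_CARTILAGE: 0.167,
                Phenotype.MARROW: 0.167,
                Phenotype.IMMATURE_BONE: 0.3,
                Phenotype.MATURE_BONE: 0.3,
                Phenotype.CORTICAL_BONE: 0.3,
            }
        )
    )
    porosity: np.ndarray = field(
        default_factory=lambda: _prop_array(
            {
                Phenotype.GRANULATION: 0.8,
                Phenotype.FIBROUS: 0.8,
                Phenotype.CARTILAGE: 0.8,
                Phenotype.CALCIFIED_CARTILAGE: 0.8,
                Phenotype.MARROW: 0.8,
                Phenotype.IMMATURE_BONE: 0.8,
                Phenotype.MATURE_BONE: 0.8,
                Phenotype.CORTICAL_BONE: 0.04,
            }
        )
    )
    fluid_viscosity: float = 1e-9  # N s/mm^2, identical for all tissues

    def __post_init__(self) -> None:
        for name in ("young", "permeability"):
            if np.any(getattr(self, name) <= 0.0):
                raise ValueError(f"{name} must be positive for every phenotype")
        if np.any(self.porosity <= 0.0) or np.any(self.porosity >= 1.0):
            raise ValueError("porosity must lie in (0, 1)")
        if np.any(self.poisson < 0.0) or np.any(self.poisson >= 0.5):
            raise ValueError("poisson ratio must lie in [0, 0.5)")
        if self.fluid_viscosity <= 0.0:
            raise ValueError("fluid_viscosity must be positive")
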