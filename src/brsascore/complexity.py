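"""Structural complexity penalty: size, stereo, ring and macrocycle terms.

The penalty captures global features that make a molecule harder to make
regardless of which fragments it contains:

* size        n_atoms^1.005 - n_atoms          (slightly superlinear in heavy atoms)
* stereo      log10(n_chiral + 1)              (assigned tetrahedral centers)
* ring        log10(n_bridgehead + 1) + log10(n_spiro + 1)
* macrocycle  log10(n_macrocycle + 1)          (SSSR rings with more than 8 atoms)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

__all__ = ["ComplexityBreakdown", "complexity_penalty", "MACROCYCLE_MIN_SIZE", "SIZE_EXPONENT"]

#: rings strictly larger than this count as macrocycles
MACROCYCLE_MIN_SIZE = 8
SIZE_EXPONENT = 1.005


@dataclass(frozen=True)
class ComplexityBreakdown:
    n_atoms: int
    n_chiral: int
    n_bridgehead: int
    n_spiro: int
    n_macrocycle: int
    size: float
    stereo: float
    ring: float
    macrocycle: float

    @property
    def total(self) -> float:
        return self.size + self.stereo + self.ring + self.macrocycle


def complexity_penalty(mol: Chem.Mol) -> ComplexityBreakdown:
    """Compute the four-term complexity penalty of a molecule.

    Only assigned chiral centers count toward the stereo term: the score
    reflects the structure as drawn, not centers that could in principle
    be resolved.
    """
    n_atoms = mol.GetNumAtoms()
    n_chiral = len(Chem.FindMolChiralCenters(mol, includeUnassigned=False, useLegacyImplementation=False))
    n_bridgehead = rdMolDescriptors.CalcNumBridgeheadAtoms(mol)
    n_spiro = rdMolDescriptors.CalcNumSpiroAtoms(mol)
    n_macrocycle = sum(
        1 for ring in mol.GetRingInfo().AtomRings() if len(ring) > MACROCYCLE_MIN_SIZE
    )
    return ComplexityBreakdown(
        n_atoms=n_atoms,
        n_chiral=n_chiral,
        n_bridgehead=n_bridgehead,
        n_spiro=n_spiro,
        n_macrocycle=n_macrocycle,
        size=n_atoms**SIZE_EXPONENT - n_atoms,
        stereo=math.log10(n_chiral + 1),
        ring=math.log10(n_bridgehead + 1) + math.log10(n_spiro + 1),
        macrocycle=math.log10(n_macrocycle + 1),
    )
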