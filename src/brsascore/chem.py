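"""Molecule / reaction parsing and per-atom circular fragment extraction.

Fragments are atom-centered circular environments (unfolded Morgan/ECFP
identifiers).  Each heavy atom of a molecule contributes one *retained*
fragment: the identifier of its largest realizable environment up to
radius 2 (the ECFP4 window).  Environments of radius 0 and 1 are excluded
from scoring because ubiquitous small fragments carry no information about
synthesizability; consequently molecules with fewer than three heavy atoms
retain no fragments at all.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from rdkit import Chem
from rdkit.Chem import rdChemReactions, rdFingerprintGenerator
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeParseError",
    "ReactionValidationError",
    "FragmentID",
    "AtomFragment",
    "MappedReaction",
    "parse_molecule",
    "canonical_smiles",
    "parse_mapped_reaction",
    "atom_environments",
    "retained_fragments",
    "iter_smiles_records",
    "iter_reaction_records",
]


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid molecule."""


class ReactionValidationError(ValueError):
    """Raised when a reaction SMILES violates the atom-mapping contract."""


@dataclass(frozen=True, slots=True, order=True)
class FragmentID:
    """Canonical identifier of an atom-centered circular environment.

    ``identifier`` is the unfolded Morgan invariant hash (full-width
    integer, no bit folding), ``radius`` the realized environment radius.
    """

    identifier: int
    radius: int


@dataclass(frozen=True, slots=True)
class AtomFragment:
    """A fragment together with the index of the atom it is centered on."""

    atom_index: int
    fragment: FragmentID


@dataclass(frozen=True)
class MappedReaction:
    """A validated atom-mapped reaction.

    Every product heavy atom carries a map number that occurs on exactly
    one reactant atom; map numbers are unique within each side.  Agents
    (the middle part of a three-component reaction SMILES) are dropped.
    """

    reactants: tuple[Chem.Mol, ...]
    products: tuple[Chem.Mol, ...]
    source_text: str = field(default="", compare=False)

    def reactant_atom_by_map(self) -> dict[int, tuple[int, int]]:
        """Map number -> (reactant index, atom index)."""
        out: dict[int, tuple[int, int]] = {}
        for ri, mol in enumerate(self.reactants):
            for atom in mol.GetAtoms():
                if atom.GetAtomMapNum() > 0:
                    out[atom.GetAtomMapNum()] = (ri, atom.GetIdx())
        return out


def parse_molecule(text: str) -> Chem.Mol:
    """Parse a SMILES string into a sanitized RDKit molecule.

    The molecule keeps its input text in the ``_source_smiles`` property;
    atom indices are stable for the lifetime of the object.
    """
    if not text or not text.strip():
        raise MoleculeParseError("empty SMILES input")
    text = text.strip()
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise MoleculeParseError(f"could not parse SMILES: {text!r}")
    mol.SetProp("_source_smiles", text)
    return mol


def canonical_smiles(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def _sanitized_copy(mol: Chem.Mol) -> Chem.Mol:
    out = Chem.Mol(mol)
    Chem.SanitizeMol(out)
    return out


def parse_mapped_reaction(text: str) -> MappedReaction:
    """Parse and validate an atom-mapped reaction SMILES.

    Requirements enforced: product heavy atoms are all mapped, map numbers
    are unique within each side, and every product map number occurs on a
    reactant atom.
    """
    if ">" not in text:
        raise ReactionValidationError(f"not a reaction SMILES (no '>'): {text!r}")
    try:
        rxn = rdChemReactions.ReactionFromSmarts(text.strip(), useSmiles=True)
    except Exception as exc:  # RDKit raises generic RuntimeError subclasses
        raise ReactionValidationError(f"could not parse reaction: {text!r} ({exc})") from exc
    if rxn is None:
        raise ReactionValidationError(f"could not parse reaction: {text!r}")
    try:
        reactants = tuple(_sanitized_copy(m) for m in rxn.GetReactants())
        products = tuple(_sanitized_copy(m) for m in rxn.GetProducts())
    except Exception as exc:
        raise ReactionValidationError(f"unsanitizable reaction component in {text!r}: {exc}") from exc

    def _maps(side: tuple[Chem.Mol, ...], name: str) -> dict[int, int]:
        seen: dict[int, int] = {}
        for mol in side:
            for atom in mol.GetAtoms():
                num = atom.GetAtomMapNum()
                if num <= 0:
                    continue
                if num in seen:
                    raise ReactionValidationError(
                        f"duplicate atom-map number {num} on {name} side of {text!r}"
                    )
                seen[num] = seen.get(num, 0) + 1
        return seen

    reactant_maps = _maps(reactants, "reactant")
    product_maps = _maps(products, "product")

    n_product_atoms = sum(m.GetNumAtoms() for m in products)
    if len(product_maps) != n_product_atoms:
        raise ReactionValidationError(f"unmapped product atom(s) in {text!r}")
    missing = set(product_maps) - set(reactant_maps)
    if missing:
        raise ReactionValidationError(
            f"product atom-map number(s) {sorted(missing)} have no reactant counterpart in {text!r}"
        )
    return MappedReaction(reactants=reactants, products=products, source_text=text.strip())


@functools.lru_cache(maxsize=8)
def _morgan_generator(radius: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius)


def atom_environments(mol: Chem.Mol, max_radius: int = 2) -> list[AtomFragment]:
    """All realized circular environments, per atom and radius.

    For each heavy atom the environments at radii 0..``max_radius`` are
    returned; an environment that stops growing (because the atom's whole
    reachable neighborhood already fits in a smaller radius) yields no
    further entries, so the largest radius present for an atom is its
    largest realizable environment.
    """
    gen = _morgan_generator(max_radius)
    out: list[AtomFragment] = []
    for idx in range(mol.GetNumAtoms()):
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitInfoMap()
        gen.GetSparseCountFingerprint(mol, fromAtoms=[idx], additionalOutput=ao)
        for identifier, hits in ao.GetBitInfoMap().items():
            for atom_idx, radius in hits:
                if atom_idx == idx:
                    out.append(AtomFragment(idx, FragmentID(identifier, radius)))
    out.sort(key=lambda af: (af.atom_index, af.fragment.radius))
    return out


def retained_fragments(mol: Chem.Mol, max_radius: int = 2) -> list[AtomFragment]:
    """The fragments kept for scoring: one per heavy atom.

    Each atom contributes the identifier of its largest realizable
    environment up to ``max_radius`` (the radius-2 slot).  Molecules with
    fewer than three heavy atoms realize only radius-0/1 environments,
    which fall under the small-fragment exclusion, so they retain nothing.
    """
    if mol.GetNumAtoms() < 3:
        return []
    envs = atom_environments(mol, max_radius)
    best: dict[int, AtomFragment] = {}
    for af in envs:
        prev = best.get(af.atom_index)
        if prev is None or af.fragment.radius > prev.fragment.radius:
            best[af.atom_index] = af
    return [best[i] for i in sorted(best)]


def iter_smiles_records(lines: Iterable[str]) -> Iterator[Chem.Mol | None]:
    """Yield molecules from .smi lines (SMILES [tab name]); ``None`` for bad lines.

    Blank lines and ``#`` comments are ignored.  Parse failures are logged
    and yielded as ``None`` so callers can count skips without aborting.
    """
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles = line.split("\t")[0].split()[0]
        try:
            yield parse_molecule(smiles)
        except MoleculeParseError:
            logger.warning("skipping unparsable SMILES at line %d: %r", lineno, smiles)
            yield None


def iter_reaction_records(lines: Iterable[str]) -> Iterator[MappedReaction | None]:
    """Yield validated mapped reactions from .rsmi lines; ``None`` for bad lines."""
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        text = line.split("\t")[0].split()[0]
        try:
            yield parse_mapped_reaction(text)
        except ReactionValidationError as exc:
            logger.warning("skipping invalid reaction at line %d: %s", lineno, exc)
            yield None
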