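"""Fragment-frequency corpora: building-block fragments and reaction-driven fragments.

Two knowledge sources feed the score table:

* **BFrags** — fragments occurring in purchasable building blocks.  Counts
  are normalized per molecule (each of a molecule's m retained fragments
  contributes 1/m), so a fragment buried in a large block counts for less
  than the same fragment in a small, versatile one.  The corpus total N_B
  is the unnormalized number of extracted fragment occurrences.

* **RFrags** — fragments centered at or near reaction centers on the
  product side of recorded reactions.  An atom at shortest bond distance d
  from the nearest center atom contributes its fragment with weight 2^-d
  for d <= 2 and nothing beyond; N_R accumulates the weighted total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from rdkit import Chem

from .chem import FragmentID, MappedReaction, retained_fragments

logger = logging.getLogger(__name__)

__all__ = [
    "CorpusError",
    "FragmentCounts",
    "ReactionCenter",
    "index_building_blocks",
    "detect_reaction_center",
    "extract_rfrags",
    "index_reactions",
    "RFRAG_MAX_DISTANCE",
]

#: two-hop window around the reaction center
RFRAG_MAX_DISTANCE = 2


class CorpusError(ValueError):
    """Raised for empty or unusable knowledge corpora."""


@dataclass
class FragmentCounts:
    """Aggregated (possibly fractional) fragment counts for one corpus.

    ``total`` is the corpus-wide fragment total (N_B or N_R) used as the
    denominator of the log-score transform.
    """

    counts: dict[FragmentID, float] = field(default_factory=dict)
    total: float = 0.0
    source: str = "building_blocks"
    n_records: int = 0
    n_skipped: int = 0

    def add(self, frag: FragmentID, weight: float) -> None:
        self.counts[frag] = self.counts.get(frag, 0.0) + weight

    def merge(self, other: "FragmentCounts") -> "FragmentCounts":
        if other.source != self.source:
            raise ValueError(f"cannot merge corpora of different sources: {self.source} vs {other.source}")
        for frag, c in other.counts.items():
            self.add(frag, c)
        self.total += other.total
        self.n_records += other.n_records
        self.n_skipped += other.n_skipped
        return self


@dataclass(frozen=True)
class ReactionCenter:
    """Product atoms whose bonding environment changed during the reaction.

    ``atoms`` holds (product index, atom index) pairs; empty only for
    identity reactions.
    """

    atoms: frozenset[tuple[int, int]]

    def __bool__(self) -> bool:
        return bool(self.atoms)


def index_building_blocks(corpus: Iterable[Chem.Mol | None]) -> FragmentCounts:
    """Stream building blocks into per-molecule-normalized fragment counts.

    ``None`` entries (upstream parse failures) are counted as skipped.
    Raises :class:`CorpusError` if no valid molecule is seen.
    """
    fc = FragmentCounts(source="building_blocks")
    for mol in corpus:
        if mol is None:
            fc.n_skipped += 1
            continue
        fc.n_records += 1
        frags = retained_fragments(mol)
        m = len(frags)
        if m == 0:
            continue
        for af in frags:
            fc.add(af.fragment, 1.0 / m)
        fc.total += m
    if fc.n_records == 0:
        raise CorpusError("building-block corpus is empty (no valid molecules)")
    return fc


def _neighbor_signature(atom: Chem.Atom) -> frozenset[tuple[int, float, int]]:
    # multiset of (neighbor map number, bond order); 0 marks unmapped neighbors
    sig: dict[tuple[int, float], int] = {}
    mol = atom.GetOwningMol()
    for bond in atom.GetBonds():
        nbr = bond.GetOtherAtom(atom)
        key = (nbr.GetAtomMapNum(), bond.GetBondTypeAsDouble())
        sig[key] = sig.get(key, 0) + 1
    return frozenset((m, o, n) for (m, o), n in sig.items())


def detect_reaction_center(rxn: MappedReaction) -> ReactionCenter:
    """Locate the reaction center by diffing bonding through the atom map.

    A product atom belongs to the center iff its multiset of
    (neighbor map number, bond order) pairs or its attached-hydrogen count
    differs from its mapped reactant counterpart, or no counterpart exists.
    """
    reactant_atoms = rxn.reactant_atom_by_map()
    center: set[tuple[int, int]] = set()
    for pi, product in enumerate(rxn.products):
        for atom in product.GetAtoms():
            map_num = atom.GetAtomMapNum()
            hit = reactant_atoms.get(map_num)
            if hit is None:
                center.add((pi, atom.GetIdx()))
                continue
            ri, ai = hit
            r_atom = rxn.reactants[ri].GetAtomWithIdx(ai)
            if (
                _neighbor_signature(atom) != _neighbor_signature(r_atom)
                or atom.GetTotalNumHs() != r_atom.GetTotalNumHs()
            ):
                center.add((pi, atom.GetIdx()))
    return ReactionCenter(atoms=frozenset(center))


def extract_rfrags(rxn: MappedReaction, center: ReactionCenter) -> FragmentCounts:
    """Distance-weighted fragments around the reaction center on the product side.

    Weight is 2^-d where d is the shortest topological distance to the
    nearest center atom within the same product molecule; atoms beyond the
    two-hop window contribute nothing.
    """
    fc = FragmentCounts(source="reactions", n_records=1)
    if not center:
        logger.warning("reaction has an empty center, contributing no fragments: %s", rxn.source_text)
        return fc
    by_product: dict[int, list[int]] = {}
    for pi, ai in center.atoms:
        by_product.setdefault(pi, []).append(ai)
    for pi, center_atoms in by_product.items():
        product = rxn.products[pi]
        frags = {af.atom_index: af.fragment for af in retained_fragments(product)}
        if not frags:
            continue
        dist = Chem.GetDistanceMatrix(product)
        for atom_idx, frag in frags.items():
            d = min(dist[atom_idx][c] for c in center_atoms)
            if d > RFRAG_MAX_DISTANCE:
                continue
            weight = 2.0 ** (-int(d))
            fc.add(frag, weight)
            fc.total += weight
    return fc


def index_reactions(corpus: Iterable[MappedReaction | None]) -> FragmentCounts:
    """Stream mapped reactions into distance-weighted fragment counts.

    ``None`` entries (upstream validation failures) are counted as
    skipped.  Raises :class:`CorpusError` if no valid reaction is seen.
    """
    fc = FragmentCounts(source="reactions")
    for rxn in corpus:
        if rxn is None:
            fc.n_skipped += 1
            continue
        fc.merge(extract_rfrags(rxn, detect_reaction_center(rxn)))
    if fc.n_records == 0:
        raise CorpusError("reaction corpus is empty (no valid reactions)")
    return fc
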