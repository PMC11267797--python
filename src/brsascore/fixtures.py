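"""Deterministic synthetic corpora: a desk-scale stand-in for real catalogs.

The generator emulates, at toy scale, the two knowledge sources a
synthesis-planning program works from: a purchasable-reagent catalog
(tens of small acids, alcohols, amines, alkyl bromides and aldehydes)
and a set of fully atom-mapped reactions obtained by applying four
bread-and-butter transformations — esterification, amide coupling, SN2
amination and reductive amination — to those reagents.  Mapped reaction
SMILES are constructed by explicit bond surgery on the mapped reactants,
so every record passes atom-map validation by construction.

It also emits a labeled query set: "ES" (easy-to-synthesize) molecules
assembled from corpus reagents via the same transformations, and "HS"
(hard-to-synthesize) molecules built around strained cages, cumulated or
conjugated multiple bonds, dense fluorination and spiro stacks — motifs
deliberately absent from the reagent catalog.

Identical (seed, sizes) inputs produce byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem

from .chem import parse_mapped_reaction, parse_molecule

__all__ = ["FixtureSpec", "FixtureError", "generate_fixture_corpus"]


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters; ``seed`` has no default on purpose."""

    seed: int
    n_building_blocks: int = 60
    n_reactions: int = 40
    n_queries_per_class: int = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise FixtureError("a seed is required; fixture generation is never nondeterministic")
        if min(self.n_building_blocks, self.n_reactions, self.n_queries_per_class) < 1:
            raise FixtureError("corpus sizes must be positive")


# -- building-block families -------------------------------------------------

# R-group prefixes; appending a functional-group suffix yields valid SMILES
_R_GROUPS = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC",
    "CC(C)", "CC(C)C", "CCC(C)", "CCCC(C)",
    "c1ccccc1", "Cc1ccccc1", "c1ccc(C)cc1", "CCc1ccccc1",
    "COCC", "CCOCC",
]
_ALKYL_R = [r for r in _R_GROUPS if r[0] == "C" and "c" not in r]

_FAMILIES: dict[str, list[str]] = {
    "acid": [r + "C(=O)O" for r in _R_GROUPS],
    "alcohol": [r + "O" for r in _R_GROUPS],
    "amine": [r + "N" for r in _R_GROUPS],
    "halide": [r + "CBr" for r in _ALKYL_R] + ["c1ccccc1CBr", "Cc1ccccc1CBr"],
    "aldehyde": [r + "C=O" for r in _R_GROUPS],
}

_SMARTS = {
    "acid": Chem.MolFromSmarts("[CX3:1](=[OX1:2])[OX2H1:3]"),
    "alcohol": Chem.MolFromSmarts("[CX4,c;!$([CX3]=O):1][OX2H:2]"),
    "amine": Chem.MolFromSmarts("[NX3;H2,H1;!$(N[C,S]=O);!$(N=*):1]"),
    "halide": Chem.MolFromSmarts("[CX4:1][Br:2]"),
    "aldehyde": Chem.MolFromSmarts("[CX3H1:1]=[OX1:2]"),
}

# hard-to-synthesize motifs: cages, cumulenes, polyynes, heavy fluorination,
# spiro stacks, peroxides — all foreign to the reagent catalog above
_HS_STRUCTURES = [
    "C12C3C4C1C5C2C3C45",
    "C1C2CC3CC1CC(C2)C3",
    "OC1C2CC3CC1CC(C2)C3",
    "C1CC2CCC1CC2",
    "C12C3C1C1C2C31",
    "C1C2C3C4C1C1C2C3C41",
    "FC(F)(F)C1CC1C(F)(F)F",
    "FC1(F)C2CC1C(F)(F)C2",
    "FC1(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C1(F)F",
    "FC(F)(F)c1cc(C(F)(F)F)cc(C(F)(F)F)c1",
    "FC1(F)C(F)(F)CCCCCCCC1",
    "C1(F)(C#N)CC1(F)C#N",
    "C=C=CC#CCO",
    "C#CC#CC#CCO",
    "C=C=C=CC#C",
    "C#CC1(O)CC(=C=C)C1",
    "OC1(C#C)CC2(CC1)OCCO2",
    "C1CC2(C1)CC1(CC2)CC2(CC1)CC2",
    "C1C2(CC2)C2(CC2)C2(CC2)C1",
    "O=C1OC(=O)C2(C1)CC1(C2)CC2(C1)CC2",
    "O1OC2CCCCC2O1",
    "O=S1(=O)CC2(C1)CC1(C2)OCC1",
    "N1(N=NN=N1)C1CC1",
    "[Si]1(C)(C)CC#CC1",
    "B1OC(C#C)CO1",
    "OC1C[C@@H](F)C[C@H](Cl)C1",
]


# -- mapped-reaction construction --------------------------------------------


def _build_mapped_rsmi(reactants: list[Chem.Mol], bond_edits) -> str:
    """Number every reactant atom, apply bond edits on the combined product, emit rsmi."""
    mols = [Chem.Mol(m) for m in reactants]
    num = 1
    for m in mols:
        for atom in m.GetAtoms():
            atom.SetAtomMapNum(num)
            num += 1
    combined = mols[0]
    offsets = [0]
    for m in mols[1:]:
        offsets.append(combined.GetNumAtoms())
        combined = Chem.CombineMols(combined, m)
    rw = Chem.RWMol(combined)
    bond_edits(rw, offsets)
    product = rw.GetMol()
    Chem.SanitizeMol(product)
    left = ".".join(Chem.MolToSmiles(m) for m in mols)
    return f"{left}>>{Chem.MolToSmiles(product)}"


def _condense(donor: Chem.Mol, partner: Chem.Mol, family: str) -> str:
    """One of the four reaction families as a mapped reaction SMILES.

    ``donor`` carries the electrophilic group (acid / halide / aldehyde),
    ``partner`` the nucleophile (alcohol or amine).  Byproducts (water,
    HBr) are left implicit: only mapped product atoms matter downstream.
    """
    if family in ("esterification", "amidation"):
        c, _, oh = donor.GetSubstructMatch(_SMARTS["acid"])
        nuc = partner.GetSubstructMatch(_SMARTS["alcohol" if family == "esterification" else "amine"])

        def edits(rw: Chem.RWMol, off: list[int]) -> None:
            rw.AddBond(off[0] + c, off[1] + nuc[-1 if family == "esterification" else 0], Chem.BondType.SINGLE)
            rw.RemoveAtom(off[0] + oh)

    elif family == "sn2":
        c, br = donor.GetSubstructMatch(_SMARTS["halide"])
        (n,) = partner.GetSubstructMatch(_SMARTS["amine"])

        def edits(rw: Chem.RWMol, off: list[int]) -> None:
            rw.AddBond(off[0] + c, off[1] + n, Chem.BondType.SINGLE)
            rw.RemoveAtom(off[0] + br)

    elif family == "reductive_amination":
        c, o = donor.GetSubstructMatch(_SMARTS["aldehyde"])
        (n,) = partner.GetSubstructMatch(_SMARTS["amine"])

        def edits(rw: Chem.RWMol, off: list[int]) -> None:
            rw.AddBond(off[0] + c, off[1] + n, Chem.BondType.SINGLE)
            rw.RemoveAtom(off[0] + o)

    else:
        raise FixtureError(f"unknown reaction family: {family}")
    return _build_mapped_rsmi([donor, partner], edits)


_REACTION_FAMILIES = [
    ("esterification", "acid", "alcohol"),
    ("amidation", "acid", "amine"),
    ("sn2", "halide", "amine"),
    ("reductive_amination", "aldehyde", "amine"),
]


def _sample_building_blocks(rng: random.Random, n: int) -> list[str]:
    # round-robin over shuffled families keeps every family represented
    pools = {fam: rng.sample(members, len(members)) for fam, members in _FAMILIES.items()}
    order = list(_FAMILIES)
    out: list[str] = []
    i = 0
    while len(out) < n:
        fam = order[i % len(order)]
        if pools[fam]:
            out.append(pools[fam].pop())
        elif not any(pools.values()):
            raise FixtureError(
                f"requested {n} building blocks but the pool holds only {len(out)}"
            )
        i += 1
    return out


def _classify(blocks: list[str]) -> dict[str, list[Chem.Mol]]:
    mols = [parse_molecule(s) for s in blocks]
    return {
        fam: [m for m in mols if m.HasSubstructMatch(_SMARTS[fam])] for fam in _SMARTS
    }


def _draw_reaction(rng: random.Random, by_group: dict[str, list[Chem.Mol]], k: int) -> str:
    family, donor_group, partner_group = _REACTION_FAMILIES[k % len(_REACTION_FAMILIES)]
    donors, partners = by_group[donor_group], by_group[partner_group]
    if not donors or not partners:
        raise FixtureError(f"no building blocks available for {family}")
    return _condense(rng.choice(donors), rng.choice(partners), family)


def generate_fixture_corpus(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write building_blocks.smi, reactions.rsmi and queries.tsv under ``out_dir``.

    Returns the three paths.  Every emitted reaction is re-validated
    through the mapped-reaction parser before writing.
    """
    rng = random.Random(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    blocks = _sample_building_blocks(rng, spec.n_building_blocks)
    by_group = _classify(blocks)

    reactions = [_draw_reaction(rng, by_group, k) for k in range(spec.n_reactions)]
    for rsmi in reactions:
        parse_mapped_reaction(rsmi)  # generator contract: always valid

    # ES queries: fresh products assembled from the same reagents, maps stripped
    es: list[str] = []
    k = 0
    while len(es) < spec.n_queries_per_class:
        if k > 100 * spec.n_queries_per_class:
            raise FixtureError("could not assemble enough distinct easy-to-synthesize queries")
        rsmi = _draw_reaction(rng, by_group, k)
        product = parse_mapped_reaction(rsmi).products[0]
        for atom in product.GetAtoms():
            atom.SetAtomMapNum(0)
        smiles = Chem.MolToSmiles(product)
        if smiles not in es:
            es.append(smiles)
        k += 1
    hs = rng.sample(_HS_STRUCTURES, min(spec.n_queries_per_class, len(_HS_STRUCTURES)))

    bb_path = out_dir / "building_blocks.smi"
    rxn_path = out_dir / "reactions.rsmi"
    query_path = out_dir / "queries.tsv"
    bb_path.write_text(
        "".join(f"{s}\tBB{i:04d}\n" for i, s in enumerate(blocks, start=1))
    )
    rxn_path.write_text("".join(f"{r}\tRX{i:04d}\n" for i, r in enumerate(reactions, start=1)))
    rows = [(f"ES{i:04d}", s, "ES") for i, s in enumerate(es, start=1)]
    rows += [(f"HS{i:04d}", s, "HS") for i, s in enumerate(hs, start=1)]
    query_path.write_text(
        "id\tsmiles\tlabel\n" + "".join(f"{i}\t{s}\t{l}\n" for i, s, l in rows)
    )
    return bb_path, rxn_path, query_path
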