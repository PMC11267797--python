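import math

import pytest
from rdkit import Chem

from brsascore import (
    CorpusError,
    detect_reaction_center,
    extract_rfrags,
    index_building_blocks,
    index_reactions,
    parse_mapped_reaction,
    parse_molecule,
    retained_fragments,
)

ESTERIFICATION = "[CH3:1][C:2](=[O:3])[OH:4].[OH:5][CH3:6]>>[CH3:1][C:2](=[O:3])[O:5][CH3:6]"
AMIDATION = "[CH3:1][C:2](=[O:3])[OH:4].[NH2:5][CH3:6]>>[CH3:1][C:2](=[O:3])[NH:5][CH3:6]"


def center_oracle(rxn):
    """Brute-force adjacency diff keyed by map numbers, built from the bond lists."""

    def side_adjacency(mols):
        adj, hs = {}, {}
        for mol in mols:
            for atom in mol.GetAtoms():
                adj.setdefault(atom.GetAtomMapNum(), [])
                hs[atom.GetAtomMapNum()] = atom.GetTotalNumHs()
            for bond in mol.GetBonds():
                a, b = bond.GetBeginAtom(), bond.GetEndAtom()
                order = bond.GetBondTypeAsDouble()
                adj[a.GetAtomMapNum()].append((b.GetAtomMapNum(), order))
                adj[b.GetAtomMapNum()].append((a.GetAtomMapNum(), order))
        return {k: sorted(v) for k, v in adj.items()}, hs

    r_adj, r_hs = side_adjacency(rxn.reactants)
    p_adj, p_hs = side_adjacency(rxn.products)
    center = set()
    for pi, product in enumerate(rxn.products):
        for atom in product.GetAtoms():
            m = atom.GetAtomMapNum()
            if m not in r_adj or p_adj[m] != r_adj[m] or p_hs[m] != r_hs[m]:
                center.add((pi, atom.GetIdx()))
    return center


def _center_maps(rxn, center):
    return {
        rxn.products[pi].GetAtomWithIdx(ai).GetAtomMapNum() for pi, ai in center.atoms
    }


class TestReactionCenter:
    def test_esterification_center(self):
        rxn = parse_mapped_reaction(ESTERIFICATION)
        assert _center_maps(rxn, detect_reaction_center(rxn)) == {2, 5}

    def test_amidation_center(self):
        rxn = parse_mapped_reaction(AMIDATION)
        assert _center_maps(rxn, detect_reaction_center(rxn)) == {2, 5}

    def test_identity_reaction_has_empty_center(self):
        rxn = parse_mapped_reaction("[CH4:1]>>[CH4:1]")
        assert not detect_reaction_center(rxn)

    def test_matches_bruteforce_oracle_on_fixture_corpus(self, fixture_reactions):
        assert len(fixture_reactions) == 40
        for rxn in fixture_reactions:
            assert detect_reaction_center(rxn).atoms == frozenset(center_oracle(rxn)), (
                rxn.source_text
            )

    def test_invariant_to_reactant_order(self):
        swapped = "[OH:5][CH3:6].[CH3:1][C:2](=[O:3])[OH:4]>>[CH3:1][C:2](=[O:3])[O:5][CH3:6]"
        a = parse_mapped_reaction(ESTERIFICATION)
        b = parse_mapped_reaction(swapped)
        assert _center_maps(a, detect_reaction_center(a)) == _center_maps(
            b, detect_reaction_center(b)
        )

    def test_invariant_to_consistent_map_renumbering(self, fixture_reactions):
        for rxn in fixture_reactions[:10]:
            maps = sorted(rxn.reactant_atom_by_map())
            relabel = {m: 100 + i for i, m in enumerate(reversed(maps))}
            text = rxn.source_text
            for old, new in relabel.items():
                text = text.replace(f":{old}]", f":x{new}]")
            text = text.replace(":x", ":")
            renumbered = parse_mapped_reaction(text)
            original = {
                rxn.products[pi].GetAtomWithIdx(ai).GetAtomMapNum()
                for pi, ai in detect_reaction_center(rxn).atoms
            }
            new_center = {
                renumbered.products[pi].GetAtomWithIdx(ai).GetAtomMapNum()
                for pi, ai in detect_reaction_center(renumbered).atoms
            }
            assert new_center == {relabel[m] for m in original}


class TestExtractRFrags:
    def test_esterification_distance_weights(self):
        rxn = parse_mapped_reaction(ESTERIFICATION)
        fc = extract_rfrags(rxn, detect_reaction_center(rxn))
        # centers C:2 and O:5 weigh 1; the three atoms one bond away weigh 1/2
        assert sorted(fc.counts.values(), reverse=True) == [1.0, 1.0, 0.5, 0.5, 0.5]
        assert fc.total == pytest.approx(3.5)
        assert fc.source == "reactions"

    def test_atoms_beyond_two_hops_contribute_nothing(self, fixture_reactions):
        for rxn in fixture_reactions:
            center = detect_reaction_center(rxn)
            fc = extract_rfrags(rxn, center)
            by_product = {}
            for pi, ai in center.atoms:
                by_product.setdefault(pi, []).append(ai)
            expected_total = 0.0
            for pi, centers in by_product.items():
                product = rxn.products[pi]
                dist = Chem.GetDistanceMatrix(product)
                for af in retained_fragments(product):
                    d = min(dist[af.atom_index][c] for c in centers)
                    if d <= 2:
                        expected_total += 2.0 ** (-d)
            assert fc.total == pytest.approx(expected_total)
            assert sum(fc.counts.values()) == pytest.approx(expected_total)

    def test_all_weights_are_inverse_powers_of_two(self, fixture_reactions):
        # every aggregated count decomposes into weights from {1, 1/2, 1/4}
        for rxn in fixture_reactions:
            fc = extract_rfrags(rxn, detect_reaction_center(rxn))
            for count in fc.counts.values():
                assert count > 0
                assert math.isclose(count * 4, round(count * 4))

    def test_identity_reaction_yields_no_fragments(self):
        rxn = parse_mapped_reaction("[CH4:1]>>[CH4:1]")
        fc = extract_rfrags(rxn, detect_reaction_center(rxn))
        assert fc.counts == {}
        assert fc.total == 0.0


class TestIndexBuildingBlocks:
    def test_per_molecule_normalization_butane(self):
        # butane: 4 retained fragments, two distinct environments twice each
        fc = index_building_blocks([parse_molecule("CCCC")])
        assert sorted(fc.counts.values()) == [0.5, 0.5]
        assert fc.total == 4.0

    def test_duplicating_corpus_doubles_counts(self, fixture_paths):
        bb_path, _, _ = fixture_paths
        mols = [parse_molecule(l.split("\t")[0]) for l in bb_path.read_text().splitlines()]
        single = index_building_blocks(mols)
        double = index_building_blocks(mols + mols)
        assert double.total == pytest.approx(2 * single.total)
        for frag, count in single.counts.items():
            assert double.counts[frag] == pytest.approx(2 * count)

    def test_contributions_sum_to_one_per_molecule(self, fixture_molecule_smiles):
        for smiles in fixture_molecule_smiles:
            mol = parse_molecule(smiles)
            if not retained_fragments(mol):
                continue
            fc = index_building_blocks([mol])
            assert sum(fc.counts.values()) == pytest.approx(1.0)

    def test_empty_corpus_raises(self):
        with pytest.raises(CorpusError):
            index_building_blocks([])

    def test_skipped_records_are_counted(self):
        fc = index_building_blocks([parse_molecule("CCCC"), None, None])
        assert fc.n_records == 1
        assert fc.n_skipped == 2


class TestIndexReactions:
    def test_single_reaction_equals_extract(self):
        rxn = parse_mapped_reaction(ESTERIFICATION)
        direct = extract_rfrags(rxn, detect_reaction_center(rxn))
        indexed = index_reactions([rxn])
        assert indexed.counts == direct.counts
        assert indexed.total == direct.total

    def test_concatenation_is_additive(self, fixture_reactions):
        first, second = fixture_reactions[:20], fixture_reactions[20:]
        a = index_reactions(first)
        b = index_reactions(second)
        both = index_reactions(fixture_reactions)
        assert both.total == pytest.approx(a.total + b.total)
        for frag in set(a.counts) | set(b.counts):
            assert both.counts[frag] == pytest.approx(
                a.counts.get(frag, 0.0) + b.counts.get(frag, 0.0)
            )

    def test_empty_corpus_raises(self):
        with pytest.raises(CorpusError):
            index_reactions([])
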