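import pytest

from brsascore import (
    FixtureSpec,
    build_score_table,
    generate_fixture_corpus,
    index_building_blocks,
    index_reactions,
)
from brsascore.chem import iter_reaction_records, iter_smiles_records

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_paths(fixture_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus")
    return generate_fixture_corpus(fixture_spec, out)


@pytest.fixture(scope="session")
def corpus_counts(fixture_paths):
    bb_path, rxn_path, _ = fixture_paths
    with open(bb_path) as fh:
        bcounts = index_building_blocks(iter_smiles_records(fh))
    with open(rxn_path) as fh:
        rcounts = index_reactions(iter_reaction_records(fh))
    return bcounts, rcounts


@pytest.fixture(scope="session")
def score_table(corpus_counts):
    return build_score_table(*corpus_counts)


@pytest.fixture(scope="session")
def fixture_reactions(fixture_paths):
    from brsascore import parse_mapped_reaction

    _, rxn_path, _ = fixture_paths
    lines = rxn_path.read_text().splitlines()
    return [parse_mapped_reaction(line.split("\t")[0]) for line in lines]


@pytest.fixture(scope="session")
def fixture_molecule_smiles(fixture_paths):
    """Building blocks plus queries: a varied pool of valid structures."""
    bb_path, _, query_path = fixture_paths
    smiles = [line.split("\t")[0] for line in bb_path.read_text().splitlines()]
    smiles += [
        line.split("\t")[1] for line in query_path.read_text().splitlines()[1:]
    ]
    return smiles


@pytest.fixture(scope="session")
def labeled_queries(fixture_paths):
    _, _, query_path = fixture_paths
    rows = [line.split("\t") for line in query_path.read_text().splitlines()[1:]]
    return [(mid, smi, label) for mid, smi, label in rows]
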