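"""Assemble the final synthetic-accessibility score and its per-atom attribution.

The fragment term averages the *negative* per-fragment scores over all n
retained fragments of the molecule (fragments scoring >= 0 contribute
zero but still count in the denominator).  Subtracting the complexity
penalty gives the raw score, which is mapped onto the familiar 1 (easy)
to 10 (hard) scale:

    normalized = 10 - 9 * (raw - (-6 - PB)) / (0 - (-6 - PB))

with PB the penalty buffer (default 1), the slack that lets complexity
differentiate molecules whose fragments are all unknown.  Values outside
[1, 10] are clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem

from .chem import FragmentID, retained_fragments
from .complexity import ComplexityBreakdown, complexity_penalty
from .scoretable import MISSING_SCORE, ScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "ScorerConfig",
    "ScoreResult",
    "br_fragment_score",
    "br_sascore",
    "normalize",
    "atom_contributions",
    "DEFAULT_PENALTY_BUFFER",
]

DEFAULT_PENALTY_BUFFER = 1.0
SCALE_BEST = 1.0
SCALE_WORST = 10.0


@dataclass(frozen=True)
class ScorerConfig:
    """Normalization settings: anchors are 0 (best raw) and -6 - penalty_buffer (worst)."""

    penalty_buffer: float = DEFAULT_PENALTY_BUFFER
    missing_score: float = MISSING_SCORE

    def __post_init__(self) -> None:
        if self.penalty_buffer < 0:
            raise ValueError(f"penalty_buffer must be >= 0, got {self.penalty_buffer}")


@dataclass
class ScoreResult:
    """Per-molecule scoring output with per-atom attributions.

    ``contributions`` maps each fragment-center atom index to the negative
    part of its fragment's score (0 for fragments scoring >= 0); darker
    rendering of more-negative atoms reproduces the usual highlight plots.
    """

    smiles: str
    fragment_scores: list[tuple[int, FragmentID, float]]
    br_fragment_score: float
    complexity: ComplexityBreakdown
    raw: float
    normalized: float
    contributions: dict[int, float] = field(default_factory=dict)


def br_fragment_score(
    mol: Chem.Mol, table: ScoreTable
) -> tuple[float, list[tuple[int, FragmentID, float]]]:
    """Average the negative fragment scores over all n retained fragments.

    Returns 0 (with a warning) for molecules that retain no fragments.
    """
    frags = retained_fragments(mol)
    scores = [(af.atom_index, af.fragment, table.lookup(af.fragment)) for af in frags]
    n = len(scores)
    if n == 0:
        logger.warning(
            "molecule retains no fragments (fewer than 3 heavy atoms); fragment score is 0: %s",
            Chem.MolToSmiles(mol),
        )
        return 0.0, []
    total = sum(s for _, _, s in scores if s < 0)
    return total / n, scores


def normalize(raw: float, penalty_buffer: float = DEFAULT_PENALTY_BUFFER) -> float:
    """Map a raw score onto [1, 10] between the anchors 0 and -6 - penalty_buffer."""
    worst = -6.0 - penalty_buffer
    value = SCALE_WORST - 9.0 * (raw - worst) / (0.0 - worst)
    return min(SCALE_WORST, max(SCALE_BEST, value))


def br_sascore(
    mol: Chem.Mol, table: ScoreTable, cfg: ScorerConfig | None = None
) -> ScoreResult:
    """Full score: fragment term minus complexity penalty, normalized to [1, 10]."""
    cfg = cfg or ScorerConfig()
    frag_score, fragment_scores = br_fragment_score(mol, table)
    cplx = complexity_penalty(mol)
    raw = frag_score - cplx.total
    normalized = normalize(raw, cfg.penalty_buffer)
    contributions = {atom: min(score, 0.0) for atom, _, score in fragment_scores}
    return ScoreResult(
        smiles=Chem.MolToSmiles(mol),
        fragment_scores=fragment_scores,
        br_fragment_score=frag_score,
        complexity=cplx,
        raw=raw,
        normalized=normalized,
        contributions=contributions,
    )


def atom_contributions(result: ScoreResult) -> dict[int, float]:
    """Negative part of each atom's fragment score; 0 marks unproblematic atoms."""
    return dict(result.contributions)
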