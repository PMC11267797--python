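"""Turn corpus fragment counts into the merged per-fragment score table.

Raw scores are ``ln(count / (0.001 * N))`` with N the corpus fragment
total, so a fragment holding exactly 0.1% of its corpus scores 0.  Counts
of at most 1 are excluded beforehand (extremely rare fragments carry more
noise than signal).  Each table (building-block and reaction) is then
linearly rescaled so its scores span [-3, 3].  A fragment's final score is
the larger of its two table entries; a fragment in neither table scores
the missing-fragment floor of -6.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .chem import FragmentID
from .knowledge import FragmentCounts

__all__ = [
    "ScoreTableError",
    "MISSING_SCORE",
    "SCALE_MIN",
    "SCALE_MAX",
    "RARE_COUNT_THRESHOLD",
    "raw_score",
    "ScoreTable",
    "build_score_table",
]

MISSING_SCORE = -6.0
SCALE_MIN = -3.0
SCALE_MAX = 3.0
#: aggregated counts at or below this are dropped before scoring
RARE_COUNT_THRESHOLD = 1.0

FORMAT_VERSION = 1


class ScoreTableError(ValueError):
    pass


def raw_score(count: float, total: float) -> float:
    """Log-frequency score of one fragment: ``ln(count / (0.001 * total))``."""
    if total <= 0:
        raise ScoreTableError(f"corpus total must be positive, got {total}")
    return math.log(count / (0.001 * total))


def _minmax_scale(raw: dict[FragmentID, float]) -> tuple[dict[FragmentID, float], float, float]:
    lo, hi = min(raw.values()), max(raw.values())
    if hi == lo:
        return {f: 0.0 for f in raw}, lo, hi
    span = (SCALE_MAX - SCALE_MIN) / (hi - lo)
    # clamp float drift so stored scores never escape the declared range
    return {
        f: min(SCALE_MAX, max(SCALE_MIN, SCALE_MIN + (v - lo) * span))
        for f, v in raw.items()
    }, lo, hi


@dataclass
class ScoreTable:
    """Merged fragment score lookup with provenance metadata.

    Stored scores lie in [-3, 3]; ``lookup`` returns the max of the
    available entries or ``missing_score`` when a fragment is unknown.
    """

    bscores: dict[FragmentID, float]
    rscores: dict[FragmentID, float]
    missing_score: float = MISSING_SCORE
    metadata: dict = field(default_factory=dict)

    def lookup(self, frag: FragmentID) -> float:
        b = self.bscores.get(frag)
        r = self.rscores.get(frag)
        if b is None and r is None:
            return self.missing_score
        if b is None:
            return r
        if r is None:
            return b
        return max(b, r)

    def __len__(self) -> int:
        return len(self.bscores) + len(self.rscores)

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        def dump(scores: dict[FragmentID, float]) -> list[list]:
            return [[f.identifier, f.radius, scores[f]] for f in sorted(scores)]

        doc = {
            "version": FORMAT_VERSION,
            "log_base": "e",
            "missing_score": self.missing_score,
            "metadata": self.metadata,
            "bscores": dump(self.bscores),
            "rscores": dump(self.rscores),
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScoreTable":
        doc = json.loads(text)
        if doc.get("version") != FORMAT_VERSION:
            raise ScoreTableError(f"unsupported score-table version: {doc.get('version')!r}")

        def load(rows: list[list]) -> dict[FragmentID, float]:
            return {FragmentID(int(i), int(r)): float(s) for i, r, s in rows}

        return cls(
            bscores=load(doc["bscores"]),
            rscores=load(doc["rscores"]),
            missing_score=float(doc["missing_score"]),
            metadata=doc.get("metadata", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ScoreTable":
        try:
            return cls.from_json(Path(path).read_text())
        except (json.JSONDecodeError, KeyError) as exc:
            raise ScoreTableError(f"malformed score-table file {path}: {exc}") from exc


def build_score_table(bcounts: FragmentCounts, rcounts: FragmentCounts) -> ScoreTable:
    """Filter rare fragments, log-transform, and rescale each corpus to [-3, 3]."""
    tables: dict[str, dict[FragmentID, float]] = {}
    anchors: dict[str, float] = {}
    for name, fc in (("b", bcounts), ("r", rcounts)):
        kept = {f: c for f, c in fc.counts.items() if c > RARE_COUNT_THRESHOLD}
        if not kept:
            raise ScoreTableError(
                f"no fragment in the {fc.source} corpus exceeds the rare-count "
                f"threshold of {RARE_COUNT_THRESHOLD}"
            )
        raw = {f: raw_score(c, fc.total) for f, c in kept.items()}
        scaled, lo, hi = _minmax_scale(raw)
        tables[name] = scaled
        anchors[f"{name}_min"], anchors[f"{name}_max"] = lo, hi
    metadata = {
        "n_building_blocks": bcounts.n_records,
        "n_reactions": rcounts.n_records,
        "n_skipped_building_blocks": bcounts.n_skipped,
        "n_skipped_reactions": rcounts.n_skipped,
        "N_B": bcounts.total,
        "N_R": rcounts.total,
        "rare_count_threshold": RARE_COUNT_THRESHOLD,
        "scaling": anchors,
        "scale_range": [SCALE_MIN, SCALE_MAX],
    }
    return ScoreTable(bscores=tables["b"], rscores=tables["r"], metadata=metadata)
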