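"""Sequence-motif census over a processed alignment.

Counts sequences matching residue patterns expressed in reference numbering
(e.g. a Pro-Pro pair in an active-site loop) and tabulates co-occurrence of
two patterns as a 2x2 contingency table.  Counts are raw sequence counts,
not redundancy-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .msa_io import AMINO_ACIDS, GAP, ProcessedAlignment, UNKNOWN


@dataclass
class PatternTerm:
    reference_position: int
    allowed_residues: frozenset[str]
    negated: bool = False

    def __post_init__(self) -> None:
        residues = frozenset(self.allowed_residues)
        if not residues or not residues <= set(AMINO_ACIDS):
            raise ValueError(
                f"allowed_residues must be a nonempty subset of the 20 amino "
                f"acids, got {sorted(self.allowed_residues)}"
            )
        self.allowed_residues = residues


@dataclass
class PatternSpec:
    terms: list[PatternTerm] = field(default_factory=list)

    @classmethod
    def from_triples(cls, triples) -> "PatternSpec":
        """Build from (ref_position, residues, negate) triples."""
        return cls(
            terms=[
                PatternTerm(int(p), frozenset(r), bool(neg))
                for p, r, neg in triples
            ]
        )


def locate_columns(
    msa: ProcessedAlignment, ref_positions: list[int]
) -> list[int]:
    """Alignment columns for reference residue numbers, order preserved."""
    cols = []
    missing = []
    for pos in ref_positions:
        try:
            cols.append(msa.position_map.column_of_residue(int(pos)))
        except KeyError:
            missing.append(int(pos))
    if missing:
        raise KeyError(
            f"reference positions not mapped (filtered out?): {missing}"
        )
    return cols


def _match_matrix(msa: ProcessedAlignment, pattern: PatternSpec) -> np.ndarray:
    """Boolean per-sequence match vector.

    A positive term requires the residue at the mapped column to be in the
    allowed set (gaps and unknowns never satisfy it).  A negated term
    requires a residue outside the set that is not a gap.
    """
    cols = locate_columns(
        msa, [t.reference_position for t in pattern.terms]
    )
    rows = msa.alignment.rows
    out = np.ones(len(rows), dtype=bool)
    for term, col in zip(pattern.terms, cols):
        chars = np.array([r[col] for r in rows])
        if term.negated:
            hit = np.isin(chars, list(term.allowed_residues), invert=True)
            hit &= chars != GAP
        else:
            hit = np.isin(chars, list(term.allowed_residues))
        out &= hit
    return out


def count_pattern(msa: ProcessedAlignment, pattern: PatternSpec) -> int:
    """Number of sequences satisfying every pattern term."""
    return int(_match_matrix(msa, pattern).sum())


def cooccurrence(
    msa: ProcessedAlignment, pattern_a: PatternSpec, pattern_b: PatternSpec
) -> np.ndarray:
    """2x2 contingency counts [[a&b, a&!b], [!a&b, !a&!b]]; sums to M."""
    ma = _match_matrix(msa, pattern_a)
    mb = _match_matrix(msa, pattern_b)
    return np.array(
        [
            [int(np.sum(ma & mb)), int(np.sum(ma & ~mb))],
            [int(np.sum(~ma & mb)), int(np.sum(~ma & ~mb))],
        ]
    )


def write_contingency(
    table: np.ndarray, path: str | Path, label_a: str = "a", label_b: str = "b"
) -> None:
    df = pd.DataFrame(
        table,
        index=[f"{label_a}", f"not_{label_a}"],
        columns=[f"{label_b}", f"not_{label_b}"],
    )
    df.to_csv(path, sep="\t", index_label="pattern")
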