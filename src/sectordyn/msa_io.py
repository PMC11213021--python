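"""Multiple sequence alignment ingestion, validation and processing.

Alignments are read through :mod:`Bio.AlignIO` (Stockholm 1.0 and FASTA),
normalised to a fixed 22-letter alphabet (20 amino acids, ``-`` gap, ``X``
unknown), and trimmed down to the columns of a chosen reference sequence so
that every retained column carries a protein residue number.  The processing
chain mirrors standard coupling-analysis practice: restrict to reference
(non-gap) columns, drop gappy columns, drop gappy and reference-divergent
sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = AMINO_ACIDS + GAP + UNKNOWN
N_AA = len(AMINO_ACIDS)
GAP_IDX = N_AA          # integer code for the gap state
UNKNOWN_IDX = N_AA + 1  # integer code for the unknown state

# Ambiguity / nonstandard residue codes collapsed onto the unknown state.
_AMBIGUOUS = set("BZJOU")


class AlignmentFormatError(ValueError):
    """Raised when an input file violates the declared alignment dialect."""


@dataclass
class Alignment:
    """An in-memory alignment over the amino-acid + gap + unknown alphabet."""

    seq_ids: list[str]
    rows: list[str]
    source_format: str = "fasta"

    def __post_init__(self) -> None:
        if len(self.rows) == 0:
            raise AlignmentFormatError("alignment contains no sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"ragged alignment: row lengths {sorted(lengths)}"
            )
        if self.n_columns < 1:
            raise AlignmentFormatError("alignment has zero columns")
        if len(self.seq_ids) != len(self.rows):
            raise AlignmentFormatError("seq_ids and rows length mismatch")
        if len(set(self.seq_ids)) != len(self.seq_ids):
            raise AlignmentFormatError("duplicate sequence identifiers")
        for sid, row in zip(self.seq_ids, self.rows):
            for pos, ch in enumerate(row):
                if ch not in ALPHABET:
                    raise AlignmentFormatError(
                        f"illegal character {ch!r} in sequence {sid!r} "
                        f"at column {pos}"
                    )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.seq_ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def to_integer_matrix(self) -> np.ndarray:
        """Encode as an (M, L) uint8 matrix; 0–19 amino acids, 20 gap, 21 X."""
        lut = np.full(128, 255, dtype=np.uint8)
        for i, aa in enumerate(AMINO_ACIDS):
            lut[ord(aa)] = i
        lut[ord(GAP)] = GAP_IDX
        lut[ord(UNKNOWN)] = UNKNOWN_IDX
        flat = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        return lut[flat].reshape(self.n_sequences, self.n_columns)


@dataclass
class PositionMap:
    """Maps 0-based alignment columns to 1-based reference residue numbers."""

    columns: np.ndarray          # int, strictly increasing
    residue_numbers: np.ndarray  # int, strictly increasing
    reference_id: str

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=int)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if self.columns.shape != self.residue_numbers.shape:
            raise ValueError("columns and residue_numbers must align")
        if self.columns.size:
            if np.any(np.diff(self.columns) <= 0):
                raise ValueError("column indices must be strictly increasing")
            if np.any(np.diff(self.residue_numbers) <= 0):
                raise ValueError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.columns)

    def residue_of_column(self, column: int) -> int:
        idx = np.searchsorted(self.columns, column)
        if idx >= len(self.columns) or self.columns[idx] != column:
            raise KeyError(f"column {column} is not mapped")
        return int(self.residue_numbers[idx])

    def column_of_residue(self, residue: int) -> int:
        idx = np.searchsorted(self.residue_numbers, residue)
        if idx >= len(self.residue_numbers) or self.residue_numbers[idx] != residue:
            raise KeyError(f"reference residue {residue} is not mapped")
        return int(self.columns[idx])


@dataclass
class ProcessingParams:
    """Thresholds for alignment trimming; all fractions in [0, 1]."""

    max_col_gap_fraction: float = 0.4
    max_seq_gap_fraction: float = 0.2
    min_ref_identity: float = 0.2
    # "union": matches / columns where at least one row is non-gap (default);
    # "mapped": matches / all mapped columns.
    identity_denominator: str = "union"

    def __post_init__(self) -> None:
        for name in ("max_col_gap_fraction", "max_seq_gap_fraction",
                     "min_ref_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.identity_denominator not in ("union", "mapped"):
            raise ValueError("identity_denominator must be 'union' or 'mapped'")


@dataclass
class ProcessedAlignment:
    alignment: Alignment
    position_map: PositionMap
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alignment.n_columns != len(self.position_map):
            raise ValueError(
                "processed alignment columns and position map disagree"
            )


def _normalize_row(raw: str, seq_id: str) -> str:
    """Upper-case, map '.'→'-', collapse ambiguity codes to 'X'."""
    out = []
    for pos, ch in enumerate(raw):
        c = ch.upper()
        if c == "." or ch == "-":
            c = GAP
        elif c in _AMBIGUOUS or c == UNKNOWN:
            c = UNKNOWN
        elif c not in AMINO_ACIDS:
            raise AlignmentFormatError(
                f"illegal character {ch!r} in sequence {seq_id!r} at column {pos}"
            )
        out.append(c)
    return "".join(out)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a Stockholm 1.0 or FASTA alignment and normalise its alphabet.

    Sequence order is preserved.  Raises :class:`AlignmentFormatError` on
    empty input, ragged records or characters outside the alphabet.
    """
    fmt = format.lower()
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    seq_ids = [rec.id for rec in msa]
    rows = [_normalize_row(str(rec.seq), rec.id) for rec in msa]
    return Alignment(seq_ids=seq_ids, rows=rows, source_format=fmt)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment as FASTA."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(alignment.seq_ids, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_position_map(pmap: PositionMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column_index\tref_residue_number\n")
        for col, res in zip(pmap.columns, pmap.residue_numbers):
            fh.write(f"{col}\t{res}\n")


def read_position_map(path: str | Path, reference_id: str = "") -> PositionMap:
    cols, resnums = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("column_index"):
            raise ValueError(f"{path}: not a position-map TSV")
        for line in fh:
            c, r = line.split()
            cols.append(int(c))
            resnums.append(int(r))
    return PositionMap(np.array(cols), np.array(resnums), reference_id)


def build_position_map(
    alignment: Alignment, reference_id: str, first_residue_number: int = 1
) -> PositionMap:
    """Map each non-gap reference column to a consecutive residue number."""
    ref_row = alignment.row(reference_id)
    columns = [i for i, ch in enumerate(ref_row) if ch != GAP]
    if not columns:
        warnings.warn(
            f"reference {reference_id!r} is all gaps; empty position map",
            stacklevel=2,
        )
    residue_numbers = [first_residue_number + k for k in range(len(columns))]
    return PositionMap(
        np.array(columns, dtype=int),
        np.array(residue_numbers, dtype=int),
        reference_id,
    )


def sequence_identity(a: str, b: str, denominator: str = "union") -> float:
    """Fractional identity between two aligned rows.

    ``union``: matches / columns where at least one row is non-gap.
    ``mapped``: matches / alignment length.
    Unknown ('X') never matches anything, including itself.
    """
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    gap = GAP.encode()
    unk = UNKNOWN.encode()
    match = (arr_a == arr_b) & (arr_a != gap) & (arr_a != unk)
    if denominator == "union":
        denom = int(np.sum((arr_a != gap) | (arr_b != gap)))
    else:
        denom = len(a)
    if denom == 0:
        return 0.0
    return float(np.sum(match)) / denom


def process_msa(
    alignment: Alignment,
    reference_id: str,
    params: ProcessingParams | None = None,
    first_residue_number: int = 1,
) -> ProcessedAlignment:
    """Trim an alignment to analysable reference positions and sequences.

    Steps, in order: (1) restrict to non-gap reference columns, then remove
    columns whose gap fraction exceeds ``max_col_gap_fraction``; (2) remove
    sequences whose gap fraction over the surviving columns exceeds
    ``max_seq_gap_fraction``; (3) remove sequences whose identity to the
    reference falls below ``min_ref_identity``.  The reference sequence is
    always retained.  'X' counts as gap for gap-fraction purposes and never
    matches in identity.
    """
    if params is None:
        params = ProcessingParams()
    ref_row = alignment.row(reference_id)
    log: dict[str, int] = {
        "input_sequences": alignment.n_sequences,
        "input_columns": alignment.n_columns,
    }

    X = alignment.to_integer_matrix()
    gapish = (X == GAP_IDX) | (X == UNKNOWN_IDX)

    # (1) columns
    ref_nongap = np.array([ch != GAP for ch in ref_row])
    log["columns_dropped_nonreference"] = int(np.sum(~ref_nongap))
    keep_cols = np.flatnonzero(ref_nongap)
    col_gap_frac = gapish[:, keep_cols].mean(axis=0)
    gappy = col_gap_frac > params.max_col_gap_fraction
    log["columns_dropped_gappy"] = int(np.sum(gappy))
    keep_cols = keep_cols[~gappy]
    if keep_cols.size == 0:
        raise ValueError("all columns removed during processing")

    # residue numbers for surviving columns, counted along the reference row
    resnum_of_col = np.cumsum(ref_nongap) - 1 + first_residue_number
    residue_numbers = resnum_of_col[keep_cols]

    # (2)–(3) sequences
    seq_gap_frac = gapish[:, keep_cols].mean(axis=1)
    ref_idx = alignment.seq_ids.index(reference_id)
    keep_seq = seq_gap_frac <= params.max_seq_gap_fraction
    log["sequences_dropped_gappy"] = int(np.sum(~keep_seq))

    trimmed_rows = ["".join(r[c] for c in keep_cols) for r in alignment.rows]
    trimmed_ref = trimmed_rows[ref_idx]
    identities = np.array(
        [
            sequence_identity(r, trimmed_ref, params.identity_denominator)
            for r in trimmed_rows
        ]
    )
    divergent = identities < params.min_ref_identity
    log["sequences_dropped_divergent"] = int(np.sum(keep_seq & divergent))
    keep_seq &= ~divergent

    if not keep_seq[ref_idx]:
        warnings.warn(
            f"reference {reference_id!r} failed a sequence filter; retained",
            stacklevel=2,
        )
        keep_seq[ref_idx] = True
    if not np.any(keep_seq):
        raise ValueError("all sequences removed during processing")

    out = Alignment(
        seq_ids=[s for s, k in zip(alignment.seq_ids, keep_seq) if k],
        rows=[r for r, k in zip(trimmed_rows, keep_seq) if k],
        source_format=alignment.source_format,
    )
    log["output_sequences"] = out.n_sequences
    log["output_columns"] = out.n_columns
    pmap = PositionMap(
        np.arange(len(keep_cols)), residue_numbers, reference_id
    )
    return ProcessedAlignment(alignment=out, position_map=pmap, filter_log=log)
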