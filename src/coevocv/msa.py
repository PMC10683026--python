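"""Multiple sequence alignment container, gap filtering and sequence weights.

The alignment is held as an integer matrix over the 20 canonical amino
acids plus the gap symbol. Column filtering keeps a ``column_map`` back to
the original alignment numbering so downstream coupling scores can always
be reported in the coordinates of the unfiltered MSA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO

logger = logging.getLogger(__name__)

#: Canonical amino-acid alphabet; the gap symbol is the last state.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
ALPHABET: str = AMINO_ACIDS + GAP
#: Alphabet size including the gap state (q = 21).
Q: int = len(ALPHABET)
GAP_STATE: int = Q - 1

_STATE_OF = {c: i for i, c in enumerate(ALPHABET)}
# Common alternate gap spellings map silently to the gap state.
_STATE_OF["."] = GAP_STATE
_STATE_OF["~"] = GAP_STATE


class AlignmentError(ValueError):
    """Raised for ragged or otherwise invalid alignments."""


@dataclass
class Msa:
    """An aligned set of sequences over the 20 amino acids plus gap.

    Attributes
    ----------
    ids : list of str
        One identifier per record.
    matrix : (n_sequences, alignment_length) int8 array
        State-encoded alignment; gap encodes as ``GAP_STATE``.
    column_map : (alignment_length,) int array
        For each retained column, its 0-based index in the original
        (unfiltered) alignment.
    """

    ids: list[str]
    matrix: np.ndarray
    column_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if self.column_map is None:
            self.column_map = np.arange(self.matrix.shape[1])
        self.column_map = np.asarray(self.column_map, dtype=int)
        if self.column_map.shape != (self.matrix.shape[1],):
            raise AlignmentError("column_map length must equal alignment length")
        if self.column_map.size and np.any(np.diff(self.column_map) <= 0):
            raise AlignmentError("column_map must be strictly increasing")
        if self.matrix.size and (self.matrix.min() < 0 or self.matrix.max() >= Q):
            raise AlignmentError(f"states must lie in [0, {Q})")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def alignment_length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, index: int) -> str:
        """Return record ``index`` as an aligned string."""
        return "".join(ALPHABET[s] for s in self.matrix[index])

    def ungapped_sequence(self, index: int) -> str:
        row = self.matrix[index]
        return "".join(ALPHABET[s] for s in row[row != GAP_STATE])

    def gap_fractions(self) -> np.ndarray:
        """Per-column fraction of gap states."""
        return (self.matrix == GAP_STATE).mean(axis=0)


def encode_sequences(ids: Sequence[str], sequences: Iterable[str]) -> Msa:
    """Build an :class:`Msa` from aligned strings.

    Unknown residue symbols (``X``, ambiguity codes, ...) are mapped to the
    gap state with a logged warning; ragged lengths raise
    :class:`AlignmentError`.
    """
    rows: list[list[int]] = []
    length: int | None = None
    unknown: set[str] = set()
    for seq_id, seq in zip(ids, sequences):
        seq = seq.upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"sequence {seq_id!r} has length {len(seq)}, expected {length}"
            )
        row = []
        for c in seq:
            state = _STATE_OF.get(c)
            if state is None:
                unknown.add(c)
                state = GAP_STATE
            row.append(state)
        rows.append(row)
    if not rows:
        raise AlignmentError("alignment contains no sequences")
    if unknown:
        logger.warning(
            "unknown residue symbols %s mapped to gap", "".join(sorted(unknown))
        )
    return Msa(ids=list(ids), matrix=np.array(rows, dtype=np.int8))


def read_msa(path: str | Path, fmt: str | None = None) -> Msa:
    """Read an alignment from FASTA or Stockholm.

    Parameters
    ----------
    path : path-like
        Alignment file.
    fmt : {"fasta", "stockholm"}, optional
        Inferred from the file extension when omitted (``.sto``/``.stk``
        mean Stockholm, everything else FASTA).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "fasta"
    fmt = fmt.lower()
    if fmt not in {"fasta", "stockholm"}:
        raise ValueError(f"unsupported alignment format {fmt!r}")
    try:
        alignment = AlignIO.read(str(path), fmt)
    except ValueError as exc:  # Biopython reports ragged records as ValueError
        raise AlignmentError(str(exc)) from exc
    return encode_sequences(
        [rec.id for rec in alignment], [str(rec.seq) for rec in alignment]
    )


def write_msa_fasta(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as handle:
        for i, seq_id in enumerate(msa.ids):
            handle.write(f">{seq_id}\n{msa.sequence(i)}\n")


def filter_columns(msa: Msa, max_gap_fraction: float = 0.2) -> Msa:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    A column with gap fraction exactly at the threshold is retained
    (columns with *more* than the threshold are filtered).
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    keep = msa.gap_fractions() <= max_gap_fraction
    if not keep.any():
        raise AlignmentError(
            f"no columns with gap fraction <= {max_gap_fraction}; nothing retained"
        )
    return Msa(
        ids=list(msa.ids),
        matrix=msa.matrix[:, keep],
        column_map=msa.column_map[keep],
    )


def sequence_weights(msa: Msa, identity_threshold: float = 0.9) -> np.ndarray:
    """Redundancy-compensating weights, one per record.

    Each sequence n receives weight 1/N, where N counts the sequences
    (including n itself) whose fractional identity with n is strictly
    above ``identity_threshold``. Identity is the fraction of matching
    columns over the full alignment length, gaps compared like any state.
    """
    if not 0.0 < identity_threshold < 1.0:
        raise ValueError("identity_threshold must lie in (0, 1)")
    m = msa.matrix
    n, length = m.shape
    counts = np.ones(n, dtype=np.int64)
    # Block the pairwise identity computation to bound memory at ~n*block.
    block = max(1, int(2**24 // max(n * length, 1)))
    for start in range(0, n, block):
        chunk = m[start : start + block]  # (b, L)
        ident = (chunk[:, None, :] == m[None, :, :]).mean(axis=2)  # (b, n)
        neighbour = ident > identity_threshold
        counts[start : start + block] = neighbour.sum(axis=1)
    return 1.0 / counts
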