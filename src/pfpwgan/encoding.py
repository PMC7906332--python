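"""Sequence I/O, filtering, and the overlapping-trigram integer encoding.

A protein sequence is represented to the model by its overlapping amino-acid
trigrams (overlap two), each mapped to one of the 20^3 = 8000 codes.  The
formal representation is a one-hot vector of length 8000 per position; since
a one-hot times an embedding matrix is a row lookup, sequences are stored as
integer index vectors with code 0 reserved for padding (codes 1..8000 are
the trigrams).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ALPHABET",
    "VOCAB_SIZE",
    "ProteinRecord",
    "read_fasta",
    "write_fasta",
    "filter_sequences",
    "trigram_index",
    "index_trigram",
    "encode_sequence",
    "decode_indices",
    "encode_batch",
    "read_feature_table",
]

#: The 20 standard amino acids, alphabetical; base-20 digit order of the code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Padding code 0 plus the 8000 trigram codes.
VOCAB_SIZE = 20 ** 3 + 1

_LETTER_ORD = {a: i for i, a in enumerate(ALPHABET)}
_LETTER_CODES = np.full(128, -1, dtype=np.int64)
for _a, _i in _LETTER_ORD.items():
    _LETTER_CODES[ord(_a)] = _i

DEFAULT_MAX_LEN = 1002


class EncodingError(ValueError):
    pass


class FastaFormatError(ValueError):
    pass


@dataclass
class ProteinRecord:
    id: str
    sequence: str


def read_fasta(path) -> list[ProteinRecord]:
    """Read FASTA records in input order; id = first header token."""
    records = [ProteinRecord(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    for r in records:
        if not r.sequence:
            raise FastaFormatError(f"record {r.id} has an empty sequence")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i:i + width] + "\n")


def filter_sequences(records, max_len: int = DEFAULT_MAX_LEN):
    """Apply the length and ambiguity filters.

    Sequences longer than ``max_len`` (1002 by default) or containing any
    character outside the 20-letter standard alphabet (B, J, O, U, X, Z, ...)
    are dropped.  Returns ``(kept, dropped)`` where ``dropped`` pairs each
    record with a reason string.
    """
    if max_len < 3:
        raise ValueError("max_len must be at least 3")
    kept, dropped = [], []
    for r in records:
        if len(r.sequence) > max_len:
            dropped.append((r, "too long"))
        elif any(ch not in _LETTER_ORD for ch in r.sequence):
            dropped.append((r, "ambiguous"))
        else:
            kept.append(r)
    return kept, dropped


def trigram_index(trigram: str) -> int:
    """Base-20 positional code of a trigram, in 1..8000 ('AAA'=1, 'YYY'=8000)."""
    if len(trigram) != 3:
        raise EncodingError(f"not a trigram: {trigram!r}")
    try:
        a, b, c = (_LETTER_ORD[ch] for ch in trigram)
    except KeyError as exc:
        raise EncodingError(f"invalid amino acid {exc.args[0]!r} in {trigram!r}") from None
    return a * 400 + b * 20 + c + 1


def index_trigram(index: int) -> str:
    """Inverse of :func:`trigram_index`."""
    if not 1 <= index <= 8000:
        raise EncodingError(f"trigram code out of range: {index}")
    v = index - 1
    return ALPHABET[v // 400] + ALPHABET[(v // 20) % 20] + ALPHABET[v % 20]


def encode_sequence(record: ProteinRecord, max_positions: int = DEFAULT_MAX_LEN - 2) -> np.ndarray:
    """Integer trigram-code vector of fixed length ``max_positions``.

    Position ``i`` holds the code of ``sequence[i:i+3]`` for ``i < L-2``;
    later positions hold the padding code 0.
    """
    L = len(record.sequence)
    if L < 3:
        raise EncodingError(f"sequence {record.id} shorter than one trigram")
    if L - 2 > max_positions:
        raise EncodingError(
            f"sequence {record.id} needs {L - 2} positions but max is {max_positions}")
    codes = _LETTER_CODES[np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = record.sequence[int(np.argmax(codes < 0))]
        raise EncodingError(f"invalid amino acid {bad!r} in {record.id}")
    out = np.zeros(max_positions, dtype=np.int64)
    out[: L - 2] = codes[:-2] * 400 + codes[1:-1] * 20 + codes[2:] + 1
    return out


def decode_indices(indices: np.ndarray) -> str:
    """Recover the sequence from its trigram codes (overlap makes this exact)."""
    nz = np.asarray(indices)
    nz = nz[nz > 0]
    if nz.size == 0:
        raise EncodingError("no trigram codes to decode")
    tri = [index_trigram(int(i)) for i in nz]
    return "".join(t[0] for t in tri) + tri[-1][1:]


def encode_batch(records, max_positions: int = DEFAULT_MAX_LEN - 2) -> np.ndarray:
    """Stack per-record encodings into an (n, max_positions) int matrix."""
    return np.stack([encode_sequence(r, max_positions) for r in records])


def read_feature_table(path):
    """Load a TSV of precomputed per-protein feature vectors.

    First column = protein id; remaining columns numeric.  Returns
    ``(ids, matrix)`` with row order preserved and the dimension inferred
    from the header.
    """
    df = pd.read_csv(path, sep="\t")
    ids = df.iloc[:, 0].astype(str).tolist()
    feats = df.iloc[:, 1:]
    try:
        matrix = feats.to_numpy(dtype=np.float64)
    except ValueError as exc:
        for col in feats.columns:
            bad = pd.to_numeric(feats[col], errors="coerce")
            if bad.isna().any():
                row = int(bad.isna().idxmax())
                raise EncodingError(
                    f"non-numeric value at row {row}, column {col!r} of {path}") from exc
        raise
    if np.isnan(matrix).any():
        row, col = map(int, np.argwhere(np.isnan(matrix))[0])
        raise EncodingError(
            f"missing value at row {row}, column {feats.columns[col]!r} of {path}")
    return ids, matrix
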