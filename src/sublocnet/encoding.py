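"""Convert amino-acid sequences into the model's two fixed-size inputs.

Two matrices are produced per protein, both padded/truncated to a fixed
number of rows ``l_max`` so every protein yields equally shaped inputs:

* a binary one-hot matrix (l_max x 23) over the 23-symbol protein alphabet
  — the 20 standard residues ACDEFGHIKLMNPQRSTVWY followed by the ambiguity
  symbols B, Z, X.  Selenocysteine U maps to C, pyrrolysine O to K, and any
  other letter (including J) to X.  Each real row sums to exactly 1; padding
  rows are all-zero.
* a real PSSM matrix (l_max x 43): the 42 numeric columns of PSI-BLAST
  ``-out_ascii_pssm`` output (20 log-odds, 20 weighted percentages,
  information content, relative gapless weight) plus one trailing constant
  zero column so that precomputed 43-column matrices load verbatim.

Sequences longer than ``l_max`` are truncated at the C-terminus; shorter
sequences are zero-padded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from sublocnet.errors import ValidationError

__all__ = [
    "CANONICAL_ALPHABET",
    "PSIBLAST_RESIDUE_ORDER",
    "EncodingConfig",
    "OneHotMatrix",
    "PSSMatrix",
    "one_hot_encode",
    "decode_one_hot",
    "parse_psiblast_pssm",
    "normalize_pssm",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

#: 20 standard residues in alphabetical order, then ambiguity codes B, Z, X.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZX"

#: Column order of the 20 log-odds / percentage columns in PSI-BLAST ASCII PSSMs.
PSIBLAST_RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWVY"

_SUBSTITUTIONS = {"U": "C", "O": "K"}


@dataclass(frozen=True)
class EncodingConfig:
    """Fixed-length encoding contract shared by both input matrices."""

    l_max: int = 1000
    alphabet: str = CANONICAL_ALPHABET
    truncation_side: str = "C-terminal"
    pssm_scaling: str = "none"  # or "sigmoid"

    def __post_init__(self) -> None:
        if self.l_max < 1:
            raise ValidationError(f"l_max must be >= 1, got {self.l_max}")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValidationError("alphabet letters must be unique")
        if self.pssm_scaling not in ("none", "sigmoid"):
            raise ValidationError(f"unknown pssm_scaling {self.pssm_scaling!r}")
        if self.truncation_side != "C-terminal":
            raise ValidationError("only C-terminal truncation is supported")


@dataclass
class OneHotMatrix:
    values: np.ndarray  # l_max x len(alphabet), binary
    true_length: int

    def __post_init__(self) -> None:
        assert self.true_length <= self.values.shape[0]


@dataclass
class PSSMatrix:
    values: np.ndarray  # l_max x 43, real
    true_length: int

    def __post_init__(self) -> None:
        assert self.true_length <= self.values.shape[0]


def _alphabet_index(config: EncodingConfig) -> dict[str, int]:
    return {a: j for j, a in enumerate(config.alphabet)}


def one_hot_encode(sequence: str, config: EncodingConfig | None = None) -> OneHotMatrix:
    """One-hot encode a sequence into an l_max x 23 binary matrix.

    Row i carries a single 1 at the alphabet index of residue a_i; letters
    outside the alphabet fall into the X column.  Non-letter characters are an
    error, as is an empty sequence.
    """
    config = config or EncodingConfig()
    if not sequence:
        raise ValidationError("empty sequence")
    sequence = sequence.upper()
    bad = [c for c in sequence if not c.isalpha()]
    if bad:
        raise ValidationError(f"non-letter characters in sequence: {bad[:5]}")
    index = _alphabet_index(config)
    x_col = index.get("X")
    if x_col is None:
        raise ValidationError("alphabet must contain the ambiguity letter X")
    true_length = min(len(sequence), config.l_max)
    mat = np.zeros((config.l_max, len(config.alphabet)), dtype=np.float64)
    for i, a in enumerate(sequence[:true_length]):
        a = _SUBSTITUTIONS.get(a, a)
        mat[i, index.get(a, x_col)] = 1.0
    return OneHotMatrix(values=mat, true_length=true_length)


def decode_one_hot(onehot: OneHotMatrix, config: EncodingConfig | None = None) -> str:
    """Inverse of one_hot_encode for sequences drawn from the alphabet itself."""
    config = config or EncodingConfig()
    rows = onehot.values[: onehot.true_length]
    if not np.all(rows.sum(axis=1) == 1):
        raise ValidationError("not a valid one-hot matrix: row sums != 1")
    cols = np.argmax(rows, axis=1)
    return "".join(config.alphabet[j] for j in cols)


_DATA_ROW = re.compile(r"^\s*(\d+)\s+([A-Za-z])\s+(.*)$")


def parse_psiblast_pssm(text: str) -> tuple[str, np.ndarray]:
    """Parse PSI-BLAST ``-out_ascii_pssm`` content.

    Returns ``(sequence, raw)`` where ``raw`` has one row per residue and the
    42 numeric columns in file order.  The recovered residue string lets the
    caller cross-check against the FASTA sequence.  Malformed data rows raise
    with the 1-based line number.
    """
    residues: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        m = _DATA_ROW.match(line)
        if not m:
            continue
        rest = m.group(3).split()
        # footer statistics lines (Lambda/K) don't match the index+residue shape;
        # anything that does match must carry exactly 42 numeric fields
        try:
            values = [float(tok) for tok in rest]
        except ValueError:
            raise ValidationError(
                f"PSSM line {lineno}: non-numeric field in {line.strip()!r}"
            ) from None
        if len(values) != 42:
            raise ValidationError(
                f"PSSM line {lineno}: expected 42 numeric columns, got {len(values)}"
            )
        residues.append(m.group(2).upper())
        rows.append(values)
    if not rows:
        raise ValidationError("no PSSM data rows found")
    return "".join(residues), np.array(rows, dtype=np.float64)


def normalize_pssm(raw: np.ndarray, config: EncodingConfig | None = None) -> PSSMatrix:
    """Pad a raw n x 42 (or n x 43) matrix to the fixed l_max x 43 shape.

    A constant-zero 43rd column is appended to 42-column input; rows are
    truncated/zero-padded to ``l_max`` exactly as in one_hot_encode.  With
    ``pssm_scaling='sigmoid'`` every entry is squashed elementwise to (0, 1).
    """
    config = config or EncodingConfig()
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2 or raw.shape[1] not in (42, 43):
        raise ValidationError(f"expected n x 42 or n x 43 matrix, got shape {raw.shape}")
    if not np.all(np.isfinite(raw)):
        raise ValidationError("non-finite entries in PSSM")
    if raw.shape[1] == 42:
        raw = np.hstack([raw, np.zeros((raw.shape[0], 1))])
    n = raw.shape[0]
    true_length = min(n, config.l_max)
    out = np.zeros((config.l_max, 43), dtype=np.float64)
    out[:true_length] = raw[:true_length]
    if config.pssm_scaling == "sigmoid":
        scaled = 1.0 / (1.0 + np.exp(-out[:true_length]))
        out[:true_length] = scaled
    return PSSMatrix(values=out, true_length=true_length)


def write_matrix_tsv(matrix: np.ndarray, path: str | Path) -> None:
    """Write a numeric matrix as TSV at full round-trip precision."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise ValidationError(f"expected a 2-D matrix, got ndim={matrix.ndim}")
    np.savetxt(path, matrix, fmt="%.17g", delimiter="\t")


def read_matrix_tsv(path: str | Path) -> np.ndarray:
    """Read a whitespace/tab-separated numeric matrix; ragged rows are an error."""
    rows: list[list[float]] = []
    width = None
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            values = [float(tok) for tok in line.split()]
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: non-numeric field") from None
        if width is None:
            width = len(values)
        elif len(values) != width:
            raise ValidationError(
                f"{path}:{lineno}: ragged row ({len(values)} fields, expected {width})"
            )
        rows.append(values)
    if not rows:
        raise ValidationError(f"{path}: empty matrix file")
    return np.array(rows, dtype=np.float64)
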