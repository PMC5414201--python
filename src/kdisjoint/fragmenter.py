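"""FASTA input, sanitization, and conversion of windows to N-code vectors.

Reads directories of (optionally gzip-compressed) FASTA files, maps every
non-ACGT character to the unknown base ``N``, slides a length-``W`` window
over each sequence, and encodes windows as vectors of ``W/N`` integer codes.
Query sequences are fragmented on the forward strand only; the taboo side is
fragmented on both strands (reverse complement included), so a query window
matching either strand of a taboo sequence is caught.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from numpy.lib.stride_tricks import sliding_window_view

from .ncode import EncodingScheme

__all__ = [
    "FASTA_EXTENSIONS",
    "SequenceRecord",
    "QueryWindow",
    "read_fasta_dir",
    "sanitize",
    "reverse_complement",
    "window_code_matrix",
    "extract_windows",
    "fragment_taboo",
]

logger = logging.getLogger(__name__)

FASTA_EXTENSIONS = (".fa", ".fasta", ".fna")

_NON_CANONICAL = re.compile(r"[^ACGNT]")
# ASCII-only case folding: str.upper() can change string length (e.g. "ß" -> "SS")
_UPPER_ASCII = str.maketrans(
    "abcdefghijklmnopqrstuvwxyz", "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
)
_RC_TABLE = str.maketrans("ACGNT", "TGCNA")
_VALID_LETTERS = re.compile(r"[ACGNT]*\Z")


@dataclass(frozen=True)
class SequenceRecord:
    """One sanitized FASTA record."""

    record_id: str
    letters: str
    source_file: str = ""

    def __len__(self) -> int:
        return len(self.letters)


@dataclass(frozen=True, slots=True)
class QueryWindow:
    """A length-``W`` query window: origin, 1-based start, letters, and codes."""

    record_id: str
    position: int
    word: str
    vector: tuple[int, ...]


def sanitize(raw: str) -> str:
    """Uppercase and replace every non-ACGT character by the unknown base N.

    IUPAC ambiguity codes, gaps and stray symbols all become ``N``; length is
    preserved.
    """
    return _NON_CANONICAL.sub("N", raw.translate(_UPPER_ASCII))


def reverse_complement(word: str) -> str:
    """Reverse complement over {A, C, G, N, T}; N maps to N."""
    if not _VALID_LETTERS.match(word):
        bad = _NON_CANONICAL.search(word).group()
        raise ValueError(f"letter {bad!r} is not one of A,C,G,N,T; sanitize first")
    return word.translate(_RC_TABLE)[::-1]


def _open_text(path: Path) -> io.TextIOBase:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _is_fasta(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(FASTA_EXTENSIONS) or name.endswith(
        tuple(ext + ".gz" for ext in FASTA_EXTENSIONS)
    )


def read_fasta_dir(path: str | Path) -> list[SequenceRecord]:
    """Read every FASTA file in a directory into sanitized records.

    Files are processed in sorted name order; records keep their within-file
    order.  The record id is the first whitespace-delimited token of the
    header.  A file whose first non-blank line is not a header is rejected
    with the file name and line number.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise ValueError(f"not a directory: {directory}")
    files = sorted(p for p in directory.iterdir() if p.is_file() and _is_fasta(p))
    if not files:
        raise ValueError(
            f"no FASTA files (extensions {', '.join(FASTA_EXTENSIONS)}, "
            f"optionally .gz) found in {directory}"
        )
    records: list[SequenceRecord] = []
    for fasta in files:
        with _open_text(fasta) as handle:
            text = handle.read()
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"malformed FASTA {fasta.name}: line {lineno} precedes any header"
                )
            break
        else:
            raise ValueError(f"malformed FASTA {fasta.name}: file contains no records")
        n_before = len(records)
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            records.append(
                SequenceRecord(
                    record_id=rec.id,
                    letters=sanitize(str(rec.seq)),
                    source_file=fasta.name,
                )
            )
        if len(records) == n_before:
            raise ValueError(f"malformed FASTA {fasta.name}: file contains no records")
    return records


def _letter_digits(letters: str, scheme: EncodingScheme) -> np.ndarray:
    arr = np.frombuffer(letters.encode("ascii"), dtype=np.uint8)
    digits = scheme.byte_lut[arr]
    if digits.size and digits.min() < 0:
        bad = letters[int(np.argmax(digits < 0))]
        raise ValueError(
            f"letter {bad!r} outside alphabet {''.join(scheme.alphabet)}; sanitize first"
        )
    return digits.astype(np.int64)


def window_code_matrix(letters: str, w: int, scheme: EncodingScheme) -> np.ndarray:
    """Encode all windows of ``letters`` as an ``(n_windows, w//n)`` int array.

    Row ``p`` (0-based) holds the N-code vector of the window starting at
    1-based position ``p + 1``.  Empty (0-row) result when the sequence is
    shorter than ``w``.
    """
    if w % scheme.n != 0:
        raise ValueError(f"W={w} is not a multiple of n={scheme.n}")
    digits = _letter_digits(letters, scheme)
    vec_len = w // scheme.n
    if len(digits) < w:
        return np.empty((0, vec_len), dtype=np.int64)
    # Code of the n-gram starting at every position, then gather each
    # window's n-gram starts (stride n within the window).
    ngram_codes = sliding_window_view(digits, scheme.n) @ scheme.powers
    starts = np.arange(len(digits) - w + 1, dtype=np.int64)
    offsets = np.arange(0, w, scheme.n, dtype=np.int64)
    return ngram_codes[starts[:, None] + offsets[None, :]]


def extract_windows(
    record: SequenceRecord, w: int, scheme: EncodingScheme
) -> list[QueryWindow]:
    """All forward-strand windows of a record, encoded; 1-based positions.

    A record shorter than ``w`` yields an empty list with a logged warning.
    """
    if len(record) < w:
        logger.warning(
            "record %s (length %d) is shorter than W=%d; no windows extracted",
            record.record_id,
            len(record),
            w,
        )
        return []
    codes = window_code_matrix(record.letters, w, scheme)
    letters = record.letters
    rid = record.record_id
    return [
        QueryWindow(
            record_id=rid,
            position=p + 1,
            word=letters[p : p + w],
            vector=tuple(row),
        )
        for p, row in enumerate(codes.tolist())
    ]


def fragment_taboo(
    records: list[SequenceRecord],
    w: int,
    scheme: EncodingScheme,
    include_reverse_complement: bool = True,
) -> list[tuple[int, ...]]:
    """Encode all taboo windows, both strands, as N-code vectors.

    For each record the forward windows and (by default) all windows of the
    reverse-complemented record are emitted, so the total vector count is
    ``2 * sum(max(0, len - w + 1))``.  Duplicates are preserved — the index
    tracks multiplicities.
    """
    vectors: list[tuple[int, ...]] = []
    for record in records:
        if len(record) < w:
            logger.warning(
                "taboo record %s (length %d) is shorter than W=%d; skipped",
                record.record_id,
                len(record),
                w,
            )
            continue
        strands = [record.letters]
        if include_reverse_complement:
            strands.append(reverse_complement(record.letters))
        for letters in strands:
            mat = window_code_matrix(letters, w, scheme)
            vectors.extend(map(tuple, mat.tolist()))
    return vectors
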