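"""N-code word encoding, the precomputed mismatch matrix, and capped distances.

A DNA word of fixed length ``N`` over an ordered alphabet maps bijectively to
its lexicographic rank, an integer in ``[0, sigma**N)`` (*N-coding*).  A
window of length ``W`` (a multiple of ``N``) then becomes a vector of
``W // N`` integer codes, and the Hamming distance between two windows is the
sum of ``W // N`` look-ups in a precomputed ``sigma**N x sigma**N`` mismatch
matrix — one byte-table read per code pair instead of ``N`` letter
comparisons.

The working alphabet is the five-letter DNA alphabet ``A < C < G < N < T``,
where ``N`` is the canonical unknown base treated as an ordinary fifth
letter (``N`` vs ``N`` counts as a match, ``N`` vs anything else as one
mismatch).  A four-letter ``A < C < G < T`` scheme is also constructible,
e.g. for worked examples on clean sequence.  ``N`` is capped at 5 because the
matrix grows as ``sigma**(2N)`` (5**10 ≈ 9.8 M single-byte entries).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DNA4",
    "DNA5",
    "VALID_N",
    "EncodingScheme",
    "MismatchMatrix",
    "choose_n",
    "encode_ngram",
    "decode_ngram",
    "build_mismatch_matrix",
    "hamming_capped",
    "neighbors_by_distance",
]

DNA5: tuple[str, ...] = ("A", "C", "G", "N", "T")
DNA4: tuple[str, ...] = ("A", "C", "G", "T")

#: Permitted code word lengths, in preference order (largest divisor wins).
VALID_N: tuple[int, ...] = (5, 4, 3)

#: The index addresses vectors by their first two codes, so W/N must be >= 2.
MIN_VECTOR_LEN = 2

_MIN_W = MIN_VECTOR_LEN * min(VALID_N)


def _is_valid_w(w: int) -> bool:
    return w >= _MIN_W and any(w % n == 0 for n in VALID_N)


def choose_n(w: int) -> int:
    """Pick the code word length ``N`` for window length ``w``.

    Returns the largest value in {5, 4, 3} that divides ``w``.  ``w`` must be
    at least 6 so that the resulting vector has the two leading codes the
    index requires.

    Raises
    ------
    ValueError
        If ``w`` is divisible by none of 3, 4, 5, or is too short; the
        message names the nearest valid window lengths.
    """
    if w < _MIN_W:
        raise ValueError(
            f"window length W={w} is too short: the smallest supported W is {_MIN_W}"
        )
    for n in VALID_N:
        if w % n == 0:
            if w // n < MIN_VECTOR_LEN:  # pragma: no cover - impossible for w >= 6
                raise ValueError(f"W={w} gives a vector shorter than {MIN_VECTOR_LEN}")
            return n
    lower = next(v for v in range(w - 1, _MIN_W - 1, -1) if _is_valid_w(v))
    upper = next(v for v in itertools.count(w + 1) if _is_valid_w(v))
    raise ValueError(
        f"window length W={w} is not a multiple of 3, 4 or 5; "
        f"nearest valid values are {lower} and {upper}"
    )


@dataclass(frozen=True)
class EncodingScheme:
    """An ordered DNA alphabet plus the code word length ``n``.

    Parameters
    ----------
    alphabet:
        Unique single letters in ascending lexicographic order.  Defaults to
        the five-letter alphabet ``A, C, G, N, T``.
    n:
        Code word length; one of 3, 4, 5.
    """

    alphabet: tuple[str, ...] = DNA5
    n: int = 3

    def __post_init__(self) -> None:
        letters = tuple(self.alphabet)
        object.__setattr__(self, "alphabet", letters)
        if len(letters) != len(set(letters)):
            raise ValueError(f"alphabet letters must be unique: {letters}")
        if any(len(c) != 1 for c in letters):
            raise ValueError(f"alphabet entries must be single letters: {letters}")
        if list(letters) != sorted(letters):
            raise ValueError(f"alphabet must be sorted ascending: {letters}")
        if self.n not in VALID_N:
            raise ValueError(f"n must be one of {sorted(VALID_N)}, got {self.n}")

    @property
    def sigma(self) -> int:
        return len(self.alphabet)

    @property
    def n_codes(self) -> int:
        """Number of distinct code words, ``sigma ** n``."""
        return self.sigma**self.n

    @cached_property
    def _rank(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.alphabet)}

    @cached_property
    def byte_lut(self) -> np.ndarray:
        """256-entry table mapping ASCII byte -> letter rank (-1 outside alphabet)."""
        lut = np.full(256, -1, dtype=np.int16)
        for i, c in enumerate(self.alphabet):
            lut[ord(c)] = i
        return lut

    @cached_property
    def powers(self) -> np.ndarray:
        """``sigma`` powers for positional encoding, most significant first."""
        return self.sigma ** np.arange(self.n - 1, -1, -1, dtype=np.int64)


def encode_ngram(word: str, scheme: EncodingScheme) -> int:
    """Lexicographic rank of ``word`` among all length-``n`` words."""
    if len(word) != scheme.n:
        raise ValueError(f"word {word!r} does not have length n={scheme.n}")
    rank = scheme._rank
    code = 0
    try:
        for c in word:
            code = code * scheme.sigma + rank[c]
    except KeyError as exc:
        raise ValueError(
            f"letter {exc.args[0]!r} in word {word!r} is outside alphabet "
            f"{''.join(scheme.alphabet)}"
        ) from None
    return code


def decode_ngram(code: int, scheme: EncodingScheme) -> str:
    """Inverse of :func:`encode_ngram`."""
    if not 0 <= code < scheme.n_codes:
        raise ValueError(f"code {code} outside [0, {scheme.n_codes})")
    letters = []
    for _ in range(scheme.n):
        code, r = divmod(code, scheme.sigma)
        letters.append(scheme.alphabet[r])
    return "".join(reversed(letters))


def _code_digits(scheme: EncodingScheme) -> np.ndarray:
    """(sigma**n, n) array: base-``sigma`` digits of every code, MSD first."""
    codes = np.arange(scheme.n_codes, dtype=np.int64)
    digits = np.empty((scheme.n_codes, scheme.n), dtype=np.uint8)
    for p in range(scheme.n):
        digits[:, p] = (codes // scheme.sigma ** (scheme.n - 1 - p)) % scheme.sigma
    return digits


@dataclass
class MismatchMatrix:
    """Dense ``sigma**n x sigma**n`` table of Hamming distances between code words.

    ``entries[i, j]`` is the letterwise Hamming distance between the words
    decoded from codes ``i`` and ``j``; each entry is a single byte.
    """

    entries: np.ndarray
    scheme: EncodingScheme
    _rows: list[list[int]] | None = field(default=None, repr=False, compare=False)
    _shells: dict[int, list[list[int]]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __getitem__(self, ij: tuple[int, int]) -> int:
        return int(self.entries[ij])

    def rows(self) -> list[list[int]]:
        """Matrix as a list of plain-int rows (fast scalar lookup in hot loops)."""
        if self._rows is None:
            self._rows = self.entries.tolist()
        return self._rows

    def shells(self, code: int) -> list[list[int]]:
        """``shells(c)[d]`` = all codes at distance exactly ``d`` from ``c``, d = 0..n."""
        cached = self._shells.get(code)
        if cached is None:
            row = self.entries[code]
            cached = [np.flatnonzero(row == d).tolist() for d in range(self.scheme.n + 1)]
            self._shells[code] = cached
        return cached


def build_mismatch_matrix(scheme: EncodingScheme) -> MismatchMatrix:
    """Precompute Hamming distances between all pairs of length-``n`` words."""
    digits = _code_digits(scheme)
    size = scheme.n_codes
    entries = np.zeros((size, size), dtype=np.uint8)
    for p in range(scheme.n):
        entries += digits[:, p][:, None] != digits[:, p][None, :]
    return MismatchMatrix(entries=entries, scheme=scheme)


def hamming_capped(
    a: Sequence[int],
    b: Sequence[int],
    cap: int,
    matrix: MismatchMatrix,
) -> int:
    """Hamming distance between two encoded windows, truncated at ``cap``.

    Sums elementwise mismatch-matrix look-ups; as soon as the running total
    exceeds ``cap`` the scan stops and ``cap + 1`` is returned, so callers may
    only rely on whether the result is ``<= cap``.
    """
    if len(a) != len(b):
        raise ValueError(f"vector lengths differ: {len(a)} vs {len(b)}")
    if cap < 0:
        raise ValueError("cap must be non-negative")
    rows = matrix.rows()
    total = 0
    for x, y in zip(a, b):
        total += rows[x][y]
        if total > cap:
            return cap + 1
    return total


def neighbors_by_distance(
    code: int, max_d: int, matrix: MismatchMatrix
) -> dict[int, list[int]]:
    """Codes grouped by exact distance from ``code``, for distances 0..``max_d``.

    Bucket ``d`` holds exactly the codes whose decoded word differs from
    ``decode(code)`` in ``d`` positions; bucket sizes are
    ``C(n, d) * (sigma - 1)**d``.
    """
    n = matrix.scheme.n
    if not 0 <= max_d <= n:
        raise ValueError(f"max_d must be in [0, {n}], got {max_d}")
    shells = matrix.shells(code)
    return {d: list(shells[d]) for d in range(max_d + 1)}
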