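"""Classification of query windows as k-disjoint or k-intersecting.

A query window is *k-disjoint* when its Hamming distance to every stored
taboo window (both strands) exceeds ``k``, and *k-intersecting* otherwise.
The engine restricts the search for each window to the candidate addresses
``(i, j)`` with ``M(x1, i) + M(x2, j) <= k`` and early-terminates every
vector comparison as soon as the running mismatch count exceeds the
remaining budget.

Self-exclusion mode supports using the same genome as query and taboo
(uniqueness-within-genome mining, e.g. CRISPR target pre-filtering): one
exact occurrence of the window's own vector is discounted, so a window is
disjoint iff it occurs exactly once and no distinct window lies within
``k``.  Note a palindromic window equals its own reverse complement, gains
multiplicity 2 from two-strand indexing, and is therefore never disjoint
under self-exclusion.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from .dictree import Dictree, Vector
from .fragmenter import QueryWindow, SequenceRecord, extract_windows
from .ncode import MismatchMatrix, choose_n

__all__ = [
    "MODES",
    "DISJOINT",
    "INTERSECTION",
    "ScanParameters",
    "WindowCall",
    "exists_within_k",
    "classify_window",
    "scan_records",
    "partition_workload",
]

logger = logging.getLogger(__name__)

MODES = ("d", "i", "a")
DISJOINT = "disjoint"
INTERSECTION = "intersection"

#: k above which the candidate-address count (and runtime) explodes; the
#: search stays exact, so larger k is allowed but warned about.
SOFT_K_LIMIT = 5


@dataclass(frozen=True)
class ScanParameters:
    """Run parameters: window length, mismatch threshold, output mode."""

    w: int
    k: int
    mode: str = "d"
    self_exclude: bool = False
    threads: int = 1

    def __post_init__(self) -> None:
        choose_n(self.w)  # validates W
        if self.k < 0:
            raise ValueError(f"k must be non-negative, got {self.k}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.threads < 1:
            raise ValueError(f"threads must be >= 1, got {self.threads}")
        if self.k > SOFT_K_LIMIT:
            logger.warning(
                "k=%d exceeds %d; the search is still exact but runtime grows "
                "roughly tenfold per extra mismatch",
                self.k,
                SOFT_K_LIMIT,
            )


@dataclass(frozen=True, slots=True)
class WindowCall:
    """Classification of one query window."""

    record_id: str
    position: int
    word: str
    label: str


def exists_within_k(
    tree: Dictree,
    x: Vector,
    k: int,
    matrix: MismatchMatrix,
    exclude_one_exact_self: bool = False,
) -> bool:
    """Is some stored vector within ``k`` mismatches of ``x``?

    With ``exclude_one_exact_self`` one exact occurrence of ``x`` itself is
    discounted: the result is then true iff ``x`` is stored at least twice,
    or some distinct vector lies within ``k``.

    Only sub-lists at candidate addresses are visited; sub-lists are scanned
    in ascending first-code distance, and every vector comparison stops as
    soon as it exceeds its remaining budget.
    """
    x = tuple(x)
    mult = tree.multiplicities.get(x, 0)
    if mult >= (2 if exclude_one_exact_self else 1):
        return True
    if k == 0:
        # Any distance-0 vector would equal x; multiplicity already decided it.
        return False

    rows = matrix.rows()
    row2 = rows[x[1]]
    index = tree.index
    length = tree.vector_length
    tail = range(2, length)
    shells = matrix.shells(x[0])
    max_d1 = min(k, matrix.scheme.n)
    for d1 in range(max_d1 + 1):
        budget1 = k - d1
        for i in shells[d1]:
            sub = index.get(i)
            if not sub:
                continue
            # Occupied second-level codes are typically far fewer than the
            # distance-<=budget1 shell around x[1]; iterate what is stored.
            for j, vecs in sub.items():
                rem = budget1 - row2[j]
                if rem < 0:
                    continue
                for y in vecs:
                    if exclude_one_exact_self and y == x:
                        continue
                    d = 0
                    for p in tail:
                        d += rows[x[p]][y[p]]
                        if d > rem:
                            break
                    else:
                        return True
    return False


def classify_window(
    window: QueryWindow,
    tree: Dictree,
    params: ScanParameters,
    matrix: MismatchMatrix,
) -> WindowCall:
    """Label one query window as disjoint or intersection."""
    hit = exists_within_k(
        tree, window.vector, params.k, matrix, params.self_exclude
    )
    return WindowCall(
        record_id=window.record_id,
        position=window.position,
        word=window.word,
        label=INTERSECTION if hit else DISJOINT,
    )


def partition_workload(n_windows: int, threads: int) -> list[tuple[int, int]]:
    """Split ``[0, n_windows)`` into <= ``threads`` contiguous ranges.

    Range sizes differ by at most one; empty ranges are dropped, so zero
    windows yields an empty list.
    """
    if threads < 1:
        raise ValueError(f"threads must be >= 1, got {threads}")
    if n_windows <= 0:
        return []
    parts = min(threads, n_windows)
    base, extra = divmod(n_windows, parts)
    ranges = []
    start = 0
    for t in range(parts):
        size = base + (1 if t < extra else 0)
        ranges.append((start, start + size))
        start += size
    return ranges


def scan_records(
    records: list[SequenceRecord],
    tree: Dictree,
    params: ScanParameters,
    matrix: MismatchMatrix,
) -> list[WindowCall]:
    """Classify every window of every record, in deterministic order.

    Output order is (record order, position) regardless of thread count:
    windows are split into contiguous chunks, each chunk is classified
    independently, and chunk results are concatenated in chunk order — each
    window's label depends only on the window itself and the index, so the
    merged output is identical for any ``threads``.
    """
    windows: list[QueryWindow] = []
    for record in records:
        windows.extend(extract_windows(record, params.w, tree.scheme))

    ranges = partition_workload(len(windows), params.threads)

    def classify_range(span: tuple[int, int]) -> list[WindowCall]:
        return [
            classify_window(windows[idx], tree, params, matrix)
            for idx in range(span[0], span[1])
        ]

    if len(ranges) <= 1:
        chunks = [classify_range(span) for span in ranges]
    else:
        with ThreadPoolExecutor(max_workers=len(ranges)) as pool:
            chunks = list(pool.map(classify_range, ranges))
    return [call for chunk in chunks for call in chunk]
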