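"""Two-level address-partitioned index over taboo N-code vectors.

Stored vectors are partitioned into sub-lists addressed by their first two
codes ``(v[0], v[1])``; e.g. every vector of the form ``<62, 3, ...>`` lands
in the sub-list at address ``(62, 3)``.  For a query vector ``x`` and
mismatch budget ``k``, only sub-lists at addresses ``(i, j)`` with
``M(x1, i) + M(x2, j) <= k`` can possibly hold a window within ``k``
mismatches, which is what makes the search sub-quadratic in practice.

The index additionally tracks the exact multiplicity of every stored vector,
which supports the self-comparison (uniqueness-within-genome) mode: there a
query window's single exact occurrence of itself must be discounted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .ncode import MIN_VECTOR_LEN, EncodingScheme, MismatchMatrix

__all__ = [
    "Dictree",
    "build_dictree",
    "insert_vector",
    "sublist_at",
    "multiplicity_of",
    "candidate_addresses",
]

Vector = tuple[int, ...]
Address = tuple[int, int]


@dataclass
class Dictree:
    """Sparse two-level index: first code -> second code -> list of vectors."""

    scheme: EncodingScheme
    w: int
    index: dict[int, dict[int, list[Vector]]] = field(default_factory=dict)
    multiplicities: Counter = field(default_factory=Counter)
    n_vectors: int = 0

    def __post_init__(self) -> None:
        if self.w % self.scheme.n != 0:
            raise ValueError(f"W={self.w} not a multiple of n={self.scheme.n}")
        if self.vector_length < MIN_VECTOR_LEN:
            raise ValueError(
                f"W={self.w}, n={self.scheme.n} gives vectors of length "
                f"{self.vector_length}; the index needs at least {MIN_VECTOR_LEN}"
            )

    @property
    def vector_length(self) -> int:
        return self.w // self.scheme.n

    def insert(self, v: Vector) -> None:
        if len(v) != self.vector_length:
            raise ValueError(
                f"vector length {len(v)} != index vector length {self.vector_length}"
            )
        v = tuple(v)
        self.index.setdefault(v[0], {}).setdefault(v[1], []).append(v)
        self.multiplicities[v] += 1
        self.n_vectors += 1

    def sublist(self, address: Address) -> list[Vector]:
        i, j = address
        return list(self.index.get(i, {}).get(j, ()))

    def multiplicity(self, v: Vector) -> int:
        return self.multiplicities.get(tuple(v), 0)

    def occupancy_histogram(self) -> dict[Address, int]:
        """Sub-list sizes by address (occupied addresses only)."""
        return {
            (i, j): len(vecs)
            for i, sub in self.index.items()
            for j, vecs in sub.items()
        }


def insert_vector(tree: Dictree, v: Vector) -> Dictree:
    tree.insert(v)
    return tree


def sublist_at(tree: Dictree, address: Address) -> list[Vector]:
    return tree.sublist(address)


def multiplicity_of(tree: Dictree, v: Vector) -> int:
    return tree.multiplicity(v)


def build_dictree(
    vectors: list[Vector], scheme: EncodingScheme, w: int
) -> Dictree:
    """Index a list of same-length N-code vectors; an empty list is valid."""
    tree = Dictree(scheme=scheme, w=w)
    for v in vectors:
        tree.insert(v)
    return tree


def candidate_addresses(
    x: Vector, k: int, matrix: MismatchMatrix
) -> set[Address]:
    """All addresses ``(i, j)`` whose sub-list could hold a within-``k`` match.

    Exactly the set ``{(i, j) : M(x1, i) + M(x2, j) <= k}``.  For ``k = 0``
    this is the singleton ``{(x1, x2)}`` — an exact match can only live in
    the query's own address.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    entries = matrix.entries
    row1 = entries[x[0]]
    row2 = entries[x[1]]
    out: set[Address] = set()
    for i in np.flatnonzero(row1 <= k):
        budget = k - int(row1[i])
        for j in np.flatnonzero(row2 <= budget):
            out.add((int(i), int(j)))
    return out
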