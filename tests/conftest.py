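"""Shared fixtures: encoding schemes, matrices, and a literal naive oracle."""

from __future__ import annotations

import pytest

from kdisjoint import (
    DNA4,
    DNA5,
    EncodingScheme,
    build_mismatch_matrix,
    reverse_complement,
)


@pytest.fixture(scope="session")
def scheme4():
    """Four-letter A<C<G<T scheme with N=3 (the worked-example scheme)."""
    return EncodingScheme(alphabet=DNA4, n=3)


@pytest.fixture(scope="session")
def scheme5():
    """Five-letter A<C<G<N<T scheme with N=3."""
    return EncodingScheme(alphabet=DNA5, n=3)


@pytest.fixture(scope="session")
def scheme5_n5():
    """Five-letter scheme with N=5 (the production default for W divisible by 5)."""
    return EncodingScheme(alphabet=DNA5, n=5)


@pytest.fixture(scope="session")
def matrix4(scheme4):
    return build_mismatch_matrix(scheme4)


@pytest.fixture(scope="session")
def matrix5(scheme5):
    return build_mismatch_matrix(scheme5)


@pytest.fixture(scope="session")
def matrix5_n5(scheme5_n5):
    return build_mismatch_matrix(scheme5_n5)


def letter_hamming(a: str, b: str) -> int:
    """Plain positionwise letter Hamming distance (test-local reference)."""
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def naive_min_hamming(query: str, taboo_letters: list[str], w: int) -> list[int]:
    """Letter-by-letter minimum distance from each query window to any taboo
    window on either strand; pure-Python loops, for tiny inputs only."""
    taboo_windows = []
    for letters in taboo_letters:
        for strand in (letters, reverse_complement(letters)):
            for i in range(len(strand) - w + 1):
                taboo_windows.append(strand[i : i + w])
    out = []
    for i in range(len(query) - w + 1):
        word = query[i : i + w]
        best = w + 1
        for tw in taboo_windows:
            d = letter_hamming(word, tw)
            if d < best:
                best = d
        out.append(best)
    return out
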