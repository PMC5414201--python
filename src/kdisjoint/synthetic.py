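"""Synthetic genomes, planted mutations, and the brute-force reference scan.

This module generates the simulated study conditions — random genomes with
planted transition substitutions (A<>G, C<>T), segment inversions, and
foreign-sequence insertions — and provides :func:`brute_force_kdisjoint`, an
exhaustive all-pairs reference that classifies query windows by direct
positionwise letter comparison against every taboo window on both strands,
with no encoding, no index and no pruning.  The reference is the ground
truth the indexed engine is tested against.

All randomness is seed-parameterized; every mutation is described by a
:class:`MutationPlan` so simulated experiments replay bit-for-bit.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .filter_engine import DISJOINT, INTERSECTION, WindowCall
from .fragmenter import SequenceRecord, reverse_complement, sanitize

__all__ = [
    "MutationPlan",
    "generate_genome",
    "sample_positions",
    "inject_substitutions",
    "inject_inversion",
    "inject_insertion",
    "min_hamming_per_window",
    "brute_force_kdisjoint",
    "recovered_sites",
    "disjoint_overlap_counts",
    "write_fasta",
    "write_plan_tsv",
    "read_plan_tsv",
]

logger = logging.getLogger(__name__)

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Transition substitution map: purine<->purine, pyrimidine<->pyrimidine.
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

_ORACLE_ALPHABET = "ACGNT"
_ORACLE_LUT = np.full(256, -1, dtype=np.int16)
for _i, _c in enumerate(_ORACLE_ALPHABET):
    _ORACLE_LUT[ord(_c)] = _i


@dataclass(frozen=True)
class MutationPlan:
    """One planted alteration, in coordinates of the *mutated* record.

    ``position`` is 1-based; ``length`` is the extent of the altered
    territory (1 for a substitution, segment length for an inversion, donor
    length for an insertion).  ``detail`` carries the donor sequence for
    insertions or a free-text note otherwise.
    """

    kind: str
    record_id: str
    position: int
    length: int
    detail: str = ""

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive interval of the altered territory."""
        return self.position, self.position + self.length - 1


def generate_genome(
    length: int, seed: int, record_id: str | None = None
) -> SequenceRecord:
    """I.i.d. uniform ACGT sequence; identical output for identical inputs."""
    if length < 1:
        raise ValueError(f"genome length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    letters = _ACGT[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    return SequenceRecord(
        record_id=record_id or f"synthetic_{length}bp_seed{seed}",
        letters=letters,
        source_file="",
    )


def sample_positions(
    length: int,
    n_sites: int,
    seed: int,
    margin: int = 0,
    min_separation: int = 1,
) -> list[int]:
    """Draw ``n_sites`` distinct 1-based positions, sorted.

    ``margin`` keeps sites at least that many letters away from both record
    ends; ``min_separation`` enforces pairwise spacing (rejection sampling,
    deterministic for a given seed).
    """
    lo, hi = 1 + margin, length - margin
    if hi - lo + 1 < n_sites:
        raise ValueError("record too short for the requested sites and margin")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for _ in range(100_000):
        cand = int(rng.integers(lo, hi + 1))
        if all(abs(cand - p) >= min_separation for p in chosen):
            chosen.append(cand)
            if len(chosen) == n_sites:
                return sorted(chosen)
    raise RuntimeError("could not place sites with the requested separation")


def _check_positions(record: SequenceRecord, positions: list[int]) -> None:
    if len(set(positions)) != len(positions):
        raise ValueError(f"positions must be distinct: {positions}")
    for p in positions:
        if not 1 <= p <= len(record):
            raise ValueError(
                f"position {p} outside record {record.record_id} (length {len(record)})"
            )


def inject_substitutions(
    record: SequenceRecord, positions: list[int]
) -> tuple[SequenceRecord, list[MutationPlan]]:
    """Apply the transition map A<>G, C<>T at each 1-based position.

    An ``N`` at a planned site is left unchanged (logged); every other
    letter is substituted, so the Hamming distance between input and output
    equals the number of non-N sites.
    """
    _check_positions(record, positions)
    letters = list(record.letters)
    plans = []
    for p in positions:
        base = letters[p - 1]
        if base == "N":
            logger.warning(
                "site %d of %s is N; transition skipped", p, record.record_id
            )
            continue
        letters[p - 1] = TRANSITION[base]
        plans.append(
            MutationPlan(
                kind="substitution",
                record_id=record.record_id,
                position=p,
                length=1,
                detail=f"{base}>{TRANSITION[base]}",
            )
        )
    mutated = SequenceRecord(record.record_id, "".join(letters), record.source_file)
    return mutated, plans


def inject_inversion(
    record: SequenceRecord, position: int, length: int
) -> tuple[SequenceRecord, MutationPlan]:
    """Replace the segment at [position, position+length-1] by its reverse complement."""
    if length < 1:
        raise ValueError("inversion length must be >= 1")
    if not (1 <= position and position + length - 1 <= len(record)):
        raise ValueError(
            f"inversion [{position}, {position + length - 1}] outside record "
            f"{record.record_id} (length {len(record)})"
        )
    s = record.letters
    segment = s[position - 1 : position - 1 + length]
    mutated_letters = s[: position - 1] + reverse_complement(segment) + s[position - 1 + length :]
    plan = MutationPlan(
        kind="inversion",
        record_id=record.record_id,
        position=position,
        length=length,
    )
    return SequenceRecord(record.record_id, mutated_letters, record.source_file), plan


def inject_insertion(
    record: SequenceRecord,
    position: int,
    donor: str,
    n_mutations: int,
    seed: int,
) -> tuple[SequenceRecord, MutationPlan]:
    """Splice ``donor`` in before the letter at 1-based ``position``.

    ``n_mutations`` distinct donor positions (chosen by ``seed``) receive a
    transition substitution before splicing; with 0 the donor appears
    verbatim.  In the mutated record the donor occupies
    ``[position, position + len(donor) - 1]``.
    """
    donor = sanitize(donor)
    if not donor:
        raise ValueError("donor must be non-empty")
    if not 1 <= position <= len(record) + 1:
        raise ValueError(
            f"insertion point {position} outside record {record.record_id} "
            f"(length {len(record)})"
        )
    if not 0 <= n_mutations <= len(donor):
        raise ValueError("n_mutations must be in [0, len(donor)]")
    rng = np.random.default_rng(seed)
    mutable = [i for i, c in enumerate(donor) if c != "N"]
    if len(mutable) < n_mutations:
        raise ValueError("donor has too few non-N letters to mutate")
    sites = sorted(rng.choice(mutable, size=n_mutations, replace=False).tolist())
    donor_letters = list(donor)
    for i in sites:
        donor_letters[i] = TRANSITION[donor_letters[i]]
    mutated_donor = "".join(donor_letters)
    s = record.letters
    mutated = SequenceRecord(
        record.record_id,
        s[: position - 1] + mutated_donor + s[position - 1 :],
        record.source_file,
    )
    plan = MutationPlan(
        kind="insertion",
        record_id=record.record_id,
        position=position,
        length=len(donor),
        detail=mutated_donor,
    )
    return mutated, plan


# ---------------------------------------------------------------------------
# Brute-force reference


def _window_digit_matrix(letters: str, w: int) -> np.ndarray:
    arr = _ORACLE_LUT[np.frombuffer(letters.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.min() < 0:
        raise ValueError("sequence contains letters outside A,C,G,N,T")
    if len(arr) < w:
        return np.empty((0, w), dtype=np.int16)
    return np.lib.stride_tricks.sliding_window_view(arr, w)


def _one_hot(mat: np.ndarray) -> np.ndarray:
    n, w = mat.shape
    eye = np.eye(len(_ORACLE_ALPHABET), dtype=np.float32)
    return eye[mat].reshape(n, w * len(_ORACLE_ALPHABET))


def min_hamming_per_window(
    query_records: list[SequenceRecord],
    taboo_records: list[SequenceRecord],
    w: int,
    chunk_rows: int = 1024,
) -> list[np.ndarray]:
    """Minimum Hamming distance from every query window to any taboo window.

    For each query record, returns an int array with one entry per window
    (1-based start ``p`` at index ``p - 1``).  Every query window is compared
    letterwise against every window of every taboo record on both strands;
    the positionwise agreement counts are evaluated for all pairs as one-hot
    inner products, so nothing is skipped and no index is consulted.  With no
    taboo window of length ``w`` at all, every distance is ``w + 1``.
    """
    taboo_parts = []
    for rec in taboo_records:
        for strand in (rec.letters, reverse_complement(rec.letters)):
            mat = _window_digit_matrix(strand, w)
            if len(mat):
                taboo_parts.append(mat)
    taboo_oh_t = None
    if taboo_parts:
        taboo = np.vstack(taboo_parts)
        taboo_oh_t = np.ascontiguousarray(_one_hot(taboo).T)

    results = []
    for rec in query_records:
        qmat = _window_digit_matrix(rec.letters, w)
        n_q = len(qmat)
        if n_q == 0 or taboo_oh_t is None:
            results.append(np.full(n_q, w + 1, dtype=np.int64))
            continue
        mins = np.empty(n_q, dtype=np.int64)
        for start in range(0, n_q, chunk_rows):
            block = _one_hot(qmat[start : start + chunk_rows])
            matches = block @ taboo_oh_t
            mins[start : start + len(block)] = w - np.rint(
                matches.max(axis=1)
            ).astype(np.int64)
        results.append(mins)
    return results


def brute_force_kdisjoint(
    query_records: list[SequenceRecord],
    taboo_records: list[SequenceRecord],
    w: int,
    k: int,
) -> list[WindowCall]:
    """Ground-truth classification by exhaustive all-pairs letter comparison.

    Quadratic in input size — intended for moderate inputs where it serves
    as the reference for the indexed engine.  Output order matches
    :func:`kdisjoint.filter_engine.scan_records`.
    """
    mins_per_record = min_hamming_per_window(query_records, taboo_records, w)
    calls: list[WindowCall] = []
    for rec, mins in zip(query_records, mins_per_record):
        for idx, dist in enumerate(mins.tolist()):
            calls.append(
                WindowCall(
                    record_id=rec.record_id,
                    position=idx + 1,
                    word=rec.letters[idx : idx + w],
                    label=DISJOINT if dist > k else INTERSECTION,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Experiment evaluation


def disjoint_overlap_counts(
    calls: list[WindowCall], plan: MutationPlan, w: int
) -> int:
    """Number of disjoint-labeled windows overlapping the plan's territory."""
    lo, hi = plan.span
    return sum(
        1
        for c in calls
        if c.label == DISJOINT
        and c.record_id == plan.record_id
        and c.position <= hi
        and c.position + w - 1 >= lo
    )


def recovered_sites(
    calls: list[WindowCall],
    plans: MutationPlan | list[MutationPlan],
    w: int,
) -> dict[tuple[str, int], bool]:
    """Per-site recovery: a planted site counts as recovered iff at least
    one disjoint-labeled window overlaps its territory."""
    if isinstance(plans, MutationPlan):
        plans = [plans]
    return {
        (p.record_id, p.position): disjoint_overlap_counts(calls, p, w) >= 1
        for p in plans
    }


# ---------------------------------------------------------------------------
# Fixture serialization (plain text, replayable)


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> Path:
    """Write records as a wrapped FASTA file."""
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.record_id}\n")
            for i in range(0, len(rec.letters), width):
                out.write(rec.letters[i : i + width] + "\n")
    return path


_PLAN_COLUMNS = ("record_id", "kind", "position", "length", "detail")


def write_plan_tsv(plans: list[MutationPlan], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(_PLAN_COLUMNS)
        for p in plans:
            writer.writerow([p.record_id, p.kind, p.position, p.length, p.detail])
    return path


def read_plan_tsv(path: str | Path) -> list[MutationPlan]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        return [
            MutationPlan(
                kind=row["kind"],
                record_id=row["record_id"],
                position=int(row["position"]),
                length=int(row["length"]),
                detail=row["detail"],
            )
            for row in reader
        ]
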