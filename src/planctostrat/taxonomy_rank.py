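"""Identity-based rank-novelty delineation of 16S rRNA query sequences.

Queries (e.g. ASVs) are compared against a type-strain reference database
with a deterministic end-gap-free global aligner; the best-hit percent
identity is mapped through the Yarza rank thresholds (98.7 / 94.5 / 86.5 /
82.0 / 78.5% for species / genus / family / order / class) to the deepest
taxonomic rank the query can share with a described taxon, and hence to a
novelty level (known species .. novel class).

The aligner is a three-state affine-gap Needleman-Wunsch with free terminal
gaps. Identity is 100 x matched columns / alignment columns, where terminal
gap columns are excluded and internal gap columns count as non-matches —
this approximates BLAST identity on near-full-length 16S comparisons while
staying fully deterministic (high-road traceback: prefer diagonal, then up,
then left, at every tie).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .io_formats import SequenceRecord

# Rank order used for shared-rank / novelty bookkeeping, deepest first.
_THRESHOLD_RANKS = ("species", "genus", "family", "order", "class")

#: shared_rank -> novelty level implied by failing to reach the next rank.
NOVELTY_OF_SHARED = {
    "species": "known_species",
    "genus": "novel_species",
    "family": "novel_genus",
    "order": "novel_family",
    "class": "novel_order",
    "none": "novel_class",
}


@dataclass(frozen=True)
class RankThresholds:
    """Minimum 16S identity (%) for membership in the same rank (Yarza)."""

    species: float = 98.7
    genus: float = 94.5
    family: float = 86.5
    order: float = 82.0
    class_: float = 78.5

    def __post_init__(self) -> None:
        vals = [self.species, self.genus, self.family, self.order, self.class_]
        if not all(a > b for a, b in zip(vals, vals[1:])):
            raise ValueError("thresholds must be strictly decreasing species > .. > class")

    def as_pairs(self) -> list[tuple[str, float]]:
        return list(zip(_THRESHOLD_RANKS,
                        (self.species, self.genus, self.family, self.order, self.class_)))


@dataclass(frozen=True)
class AlignmentParams:
    """Pairwise DNA alignment scoring (classic +5/-4 with affine gaps)."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -0.5
    end_gaps_free: bool = True

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0 < self.match):
            raise ValueError("require gap_open <= gap_extend <= 0 < match")


@dataclass(frozen=True)
class NoveltyCall:
    """Best-hit identity and the rank-novelty inference for one query."""

    query_id: str
    best_hit_id: str
    identity: float
    shared_rank: str
    novelty: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")
        if NOVELTY_OF_SHARED.get(self.shared_rank) != self.novelty:
            raise ValueError(
                f"novelty {self.novelty!r} inconsistent with shared rank {self.shared_rank!r}"
            )


# ---------------------------------------------------------------------------
# Alignment kernel
# ---------------------------------------------------------------------------

_NEG = -1e18


@njit(cache=True)
def _align_kernel(q, s, match, mismatch, go, ge, free_ends):  # pragma: no cover
    n = q.shape[0]
    m = s.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in query (left move, consumes subject)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in subject (up move, consumes query)

    if free_ends:
        for j in range(m + 1):
            M[0, j] = 0.0
        for i in range(n + 1):
            M[i, 0] = 0.0
    else:
        M[0, 0] = 0.0
        for j in range(1, m + 1):
            X[0, j] = go + (j - 1) * ge
        for i in range(1, n + 1):
            Y[i, 0] = go + (i - 1) * ge

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if q[i - 1] == s[j - 1] else mismatch
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = sub + best

            y = M[i - 1, j] + go
            if Y[i - 1, j] + ge > y:
                y = Y[i - 1, j] + ge
            if X[i - 1, j] + go > y:
                y = X[i - 1, j] + go
            Y[i, j] = y

            x = M[i, j - 1] + go
            if X[i, j - 1] + ge > x:
                x = X[i, j - 1] + ge
            if Y[i, j - 1] + go > x:
                x = Y[i, j - 1] + go
            X[i, j] = x

    # End cell: corner first, then last row right-to-left, then last column
    # bottom-to-top; strictly greater scores win, so the scan order is the
    # deterministic tie-break.
    ei, ej = n, m
    def _h(i, j):
        v = M[i, j]
        if Y[i, j] > v:
            v = Y[i, j]
        if X[i, j] > v:
            v = X[i, j]
        return v

    best = _h(n, m)
    if free_ends:
        for j in range(m - 1, 0, -1):
            v = _h(n, j)
            if v > best:
                best, ei, ej = v, n, j
        for i in range(n - 1, 0, -1):
            v = _h(i, m)
            if v > best:
                best, ei, ej = v, i, m

    # Traceback with preference M (diagonal) > Y (up) > X (left).
    eps = 1e-9
    i, j = ei, ej
    if M[i, j] >= best - eps:
        state = 0
    elif Y[i, j] >= best - eps:
        state = 1
    else:
        state = 2

    matches = 0
    columns = 0
    while i > 0 or j > 0:
        if state == 0:  # diagonal
            if i == 0 or j == 0:
                break  # free leading gap boundary
            target = M[i, j]
            sub = match if q[i - 1] == s[j - 1] else mismatch
            columns += 1
            if q[i - 1] == s[j - 1]:
                matches += 1
            prev = target - sub
            i -= 1
            j -= 1
            if i == 0 or j == 0:
                if free_ends:
                    break
                # global mode: fall through to boundary gap states below
            if M[i, j] >= prev - eps:
                state = 0
            elif Y[i, j] >= prev - eps:
                state = 1
            else:
                state = 2
            if not free_ends and (i == 0 or j == 0):
                if i == 0 and j > 0:
                    state = 2
                elif j == 0 and i > 0:
                    state = 1
                elif i == 0 and j == 0:
                    break
        elif state == 1:  # up: q[i-1] against a gap
            target = Y[i, j]
            columns += 1
            i -= 1
            if i == 0 and free_ends:
                break
            if i == 0 and j == 0:
                break
            if M[i, j] + go >= target - eps:
                state = 0
            elif Y[i, j] + ge >= target - eps:
                state = 1
            else:
                state = 2
            if not free_ends and i == 0 and j > 0:
                state = 2
        else:  # left: s[j-1] against a gap
            target = X[i, j]
            columns += 1
            j -= 1
            if j == 0 and free_ends:
                break
            if i == 0 and j == 0:
                break
            if M[i, j] + go >= target - eps:
                state = 0
            elif X[i, j] + ge >= target - eps:
                state = 2
            else:
                state = 1
            if not free_ends and j == 0 and i > 0:
                state = 1

    return best, float(matches), float(columns)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def align_identity(
    query: SequenceRecord,
    subject: SequenceRecord,
    params: AlignmentParams = AlignmentParams(),
    min_length: int = 100,
) -> tuple[float, int]:
    """Percent identity and alignment length of the optimal alignment.

    Terminal-gap columns are excluded from both numbers; internal gap columns
    count as non-matching columns.
    """
    for rec in (query, subject):
        if len(rec.seq) < min_length:
            raise ValueError(
                f"sequence {rec.id!r} shorter than {min_length} bases"
            )
    score, matches, columns = _align_kernel(
        _encode(query.seq), _encode(subject.seq),
        params.match, params.mismatch, params.gap_open, params.gap_extend,
        params.end_gaps_free,
    )
    if columns == 0:
        return 0.0, 0
    return 100.0 * matches / columns, int(columns)


def align_score(
    query: SequenceRecord,
    subject: SequenceRecord,
    params: AlignmentParams = AlignmentParams(),
    min_length: int = 100,
) -> float:
    """Optimal alignment score under ``params`` (same DP as align_identity)."""
    for rec in (query, subject):
        if len(rec.seq) < min_length:
            raise ValueError(f"sequence {rec.id!r} shorter than {min_length} bases")
    score, _, _ = _align_kernel(
        _encode(query.seq), _encode(subject.seq),
        params.match, params.mismatch, params.gap_open, params.gap_extend,
        params.end_gaps_free,
    )
    return float(score)


# ---------------------------------------------------------------------------
# Best hit and delineation
# ---------------------------------------------------------------------------

def best_hit(
    query: SequenceRecord,
    reference_db: Iterable[SequenceRecord],
    params: AlignmentParams = AlignmentParams(),
    min_length: int = 100,
) -> tuple[str, float]:
    """Database subject maximizing identity; ties go to the smallest id."""
    db = list(reference_db)
    if not db:
        raise ValueError("empty reference database")
    best_id, best_identity = None, -1.0
    for subject in sorted(db, key=lambda r: r.id):
        identity, _ = align_identity(query, subject, params, min_length)
        if identity > best_identity + 1e-12:
            best_id, best_identity = subject.id, identity
    return best_id, best_identity


def delineate(
    identity: float, thresholds: RankThresholds = RankThresholds()
) -> tuple[str, str]:
    """Map a percent identity to (deepest shared rank, novelty level).

    Boundaries are inclusive: identity equal to a threshold shares that rank.
    """
    if not 0.0 <= identity <= 100.0:
        raise ValueError(f"identity {identity} outside [0, 100]")
    for rank, thr in thresholds.as_pairs():
        if identity >= thr:
            return rank, NOVELTY_OF_SHARED[rank]
    return "none", NOVELTY_OF_SHARED["none"]


def classify_queries(
    queries: Iterable[SequenceRecord],
    reference_db: Sequence[SequenceRecord],
    params: AlignmentParams = AlignmentParams(),
    thresholds: RankThresholds = RankThresholds(),
    min_length: int = 100,
) -> tuple[list[NoveltyCall], dict[str, dict[str, float]]]:
    """Call novelty for each query and summarize unknowns per rank.

    The summary gives, for each rank, the count and percentage of queries NOT
    classifiable at that rank (novelty strictly deeper), e.g. the share of
    queries "unknown at genus level".
    """
    calls: list[NoveltyCall] = []
    for q in queries:
        sid, identity = best_hit(q, reference_db, params, min_length)
        shared, novelty = delineate(identity, thresholds)
        calls.append(NoveltyCall(
            query_id=q.id, best_hit_id=sid, identity=identity,
            shared_rank=shared, novelty=novelty,
        ))

    depth = {"species": 5, "genus": 4, "family": 3, "order": 2, "class": 1, "none": 0}
    n = len(calls)
    summary: dict[str, dict[str, float]] = {}
    for rank in _THRESHOLD_RANKS:
        unknown = sum(1 for c in calls if depth[c.shared_rank] < depth[rank])
        summary[rank] = {
            "n_unknown": unknown,
            "pct_unknown": (100.0 * unknown / n) if n else 0.0,
        }
    return calls, summary


def calls_to_frame(calls: Sequence[NoveltyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": c.query_id,
                "best_hit_id": c.best_hit_id,
                "identity": c.identity,
                "shared_rank": c.shared_rank,
                "novelty": c.novelty,
            }
            for c in calls
        ],
        columns=["query_id", "best_hit_id", "identity", "shared_rank", "novelty"],
    )
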