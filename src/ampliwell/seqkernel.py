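"""Pairwise sequence comparison primitives shared by every pipeline stage.

Three operations cover all downstream needs:

* :func:`global_identity` — semi-global percent identity between two
  nucleotide sequences.  Terminal gaps are excluded from the scored
  columns, so a short fragment (e.g. a ~250 nt V4 region) fully contained
  in a near-full-length 16S sequence at an exact match scores 100.
* :func:`oligo_search` — all ungapped occurrences of a short oligo
  (primer/adapter/barcode) on either strand with a mismatch budget.
* :func:`db_search` — best database hit above an identity threshold.

A single identity definition — ``100 * matches / scored_columns`` with
terminal gaps free, internal gaps counted as non-match columns and ``N``
matching nothing — is used everywhere: the 97% reliability/clustering/
cross-reference thresholds and the 75% nonspecific threshold all consume
this quantity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

_VALID_RE = re.compile(r"^[ACGTNacgtn]+$")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Alignment engine: unit-cost edit-distance alignment (edlib) in infix
# ("HW") mode with the shorter sequence as the query, which realises the
# free-terminal-gap policy.  The minimum-edit path also maximises identity
# for all practical purposes at the divergences this pipeline operates at.
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or characters outside {A,C,G,T,N}."""


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a semi-global pairwise alignment.

    ``identity`` is ``100 * matches / columns`` where ``columns`` counts
    every alignment column except terminal gaps.
    """

    identity: float
    matches: int
    columns: int
    query_strand: str  # "plus" | "minus"


@dataclass(frozen=True)
class OligoHit:
    """Ungapped occurrence of an oligo on a query sequence.

    Coordinates are 0-based, half-open, always on the plus representation
    of the query; ``strand == "minus"`` means the reverse complement of
    the oligo matched there.
    """

    start: int
    end: int
    mismatches: int
    strand: str


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_seq(seq: str, name: str) -> str:
    if not seq:
        raise InvalidSequenceError(f"{name} sequence is empty")
    if not _VALID_RE.match(seq):
        raise InvalidSequenceError(
            f"{name} sequence contains characters outside A/C/G/T/N"
        )
    return seq.upper()


def _mask_n(query: str, target: str) -> tuple[str, str]:
    # N must match nothing, including another N; map the two sides to
    # distinct placeholder letters so edlib never equates them.
    return query.replace("N", "P"), target.replace("N", "Q")


def _cigar_stats(cigar: str) -> tuple[int, int]:
    matches = 0
    columns = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def _align_one_strand(query: str, target: str) -> tuple[int, int]:
    q, t = _mask_n(query, target)
    res = edlib.align(q, t, mode="HW", task="path")
    return _cigar_stats(res["cigar"])


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    # Shorter sequence as query (free terminal gaps belong to the longer
    # side); equal lengths tie-break on content so the operation is
    # symmetric in its arguments.
    if len(a) < len(b) or (len(a) == len(b) and a <= b):
        return a, b
    return b, a


def _identity(query: str, target: str, both_strands: bool) -> AlignmentResult:
    m_plus, c_plus = _align_one_strand(query, target)
    id_plus = m_plus / c_plus if c_plus else 0.0
    if not both_strands:
        return AlignmentResult(100.0 * id_plus, m_plus, c_plus, "plus")
    m_minus, c_minus = _align_one_strand(reverse_complement(query), target)
    id_minus = m_minus / c_minus if c_minus else 0.0
    if id_minus > id_plus:
        return AlignmentResult(100.0 * id_minus, m_minus, c_minus, "minus")
    return AlignmentResult(100.0 * id_plus, m_plus, c_plus, "plus")


def global_identity(a: str, b: str, both_strands: bool = True) -> AlignmentResult:
    """Semi-global percent identity between two nucleotide sequences.

    The shorter sequence is aligned inside the longer one with terminal
    gaps excluded from scoring; both strands of the shorter sequence are
    tried (unless ``both_strands`` is off, for pre-oriented inputs) and
    the better one reported.  Symmetric in its arguments.
    """
    a = _check_seq(a, "first")
    b = _check_seq(b, "second")
    query, target = _canonical_pair(a, b)
    return _identity(query, target, both_strands)


def identity_if_at_least(
    a: str, b: str, threshold: float, both_strands: bool = True
) -> float | None:
    """Exact identity if it can reach ``threshold``, else ``None`` fast.

    A bounded edit-distance screen rejects clearly-below-threshold pairs
    in microseconds; plausible pairs get the exact path alignment.  A
    returned float is the exact identity (it may still be below the
    threshold); ``None`` guarantees identity < threshold.
    """
    a = _check_seq(a, "first")
    b = _check_seq(b, "second")
    query, target = _canonical_pair(a, b)
    d_max = _distance_bound(len(query), threshold)
    d = _screen_distance(query, target, d_max)
    if both_strands and d < 0:
        d = _screen_distance(reverse_complement(query), target, d_max)
    if d < 0:
        return None
    return _identity(query, target, both_strands).identity


_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str, n_code: int) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.uint8)
    for base, code in _ENCODE.items():
        out[arr == ord(base)] = code if base != "N" else n_code
    return out


def _scan_one_strand(
    query_enc: np.ndarray, oligo: str, max_mismatches: int, strand: str
) -> list[OligoHit]:
    k = len(oligo)
    if k > query_enc.size:
        return []
    # N in the oligo gets a different code than N in the query, so N never
    # matches anything on either side.
    oligo_enc = _encode(oligo, n_code=5)
    windows = np.lib.stride_tricks.sliding_window_view(query_enc, k)
    mm = (windows != oligo_enc).sum(axis=1)
    starts = np.nonzero(mm <= max_mismatches)[0]
    return [OligoHit(int(s), int(s) + k, int(mm[s]), strand) for s in starts]


def oligo_search(
    query: str,
    oligo: str,
    max_mismatches: int,
    strands: str = "both",
) -> list[OligoHit]:
    """All ungapped occurrences of ``oligo`` on ``query`` with at most
    ``max_mismatches`` substitutions, sorted by mismatches then position.

    ``strands`` may be ``"both"`` (default), ``"plus"`` or ``"minus"``.
    An oligo longer than the query yields an empty list.
    """
    query = _check_seq(query, "query")
    oligo = _check_seq(oligo, "oligo")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    query_enc = _encode(query, n_code=4)
    hits: list[OligoHit] = []
    if strands in ("both", "plus"):
        hits += _scan_one_strand(query_enc, oligo, max_mismatches, "plus")
    if strands in ("both", "minus"):
        hits += _scan_one_strand(
            query_enc, reverse_complement(oligo), max_mismatches, "minus"
        )
    hits.sort(key=lambda h: (h.mismatches, h.start, h.strand))
    return hits


class EmptyDatabaseError(ValueError):
    """db_search against an empty reference set is a configuration error."""


@dataclass(frozen=True)
class DbHit:
    hit_id: str
    alignment: AlignmentResult


def _kmer_set(seq: str, k: int) -> set[int]:
    enc = _encode(seq.upper(), n_code=4)
    if enc.size < k:
        return set()
    weights = 4 ** np.arange(k, dtype=np.int64)[::-1]
    windows = np.lib.stride_tricks.sliding_window_view(enc, k)
    valid = (windows < 4).all(axis=1)
    codes = (windows[valid].astype(np.int64) * weights).sum(axis=1)
    return set(codes.tolist())


def _distance_bound(query_len: int, threshold: float) -> int:
    # identity >= t implies dist <= cols*(1-t) and cols <= |q| + dist,
    # hence dist <= |q|*(1-t)/t.
    t = threshold / 100.0
    return int(np.ceil(query_len * (1.0 - t) / t)) + 1


def _screen_distance(query: str, target: str, k: int) -> int:
    q, t = _mask_n(query.upper(), target.upper())
    res = edlib.align(q, t, mode="HW", task="distance", k=k)
    d = res["editDistance"]
    return d if d >= 0 else -1


def db_search(
    query: str,
    database: Sequence[tuple[str, str]],
    identity_threshold: float | None = 97.0,
    prescreen_kmer: int = 12,
    both_strands: bool = True,
) -> DbHit | None:
    """Best database hit for ``query`` (records are ``(id, sequence)``).

    Returns the record with maximal semi-global identity if that identity
    is at or above ``identity_threshold``, else ``None``.  With
    ``identity_threshold=None`` the best hit is returned unconditionally.
    Ties are broken by database input order.

    A shared-k-mer prescreen is applied only when the pigeonhole bound
    guarantees it cannot discard a record at or above the threshold.
    """
    if not database:
        raise EmptyDatabaseError("reference database is empty")
    query = _check_seq(query, "query")
    if identity_threshold is not None and not (0.0 < identity_threshold <= 100.0):
        raise ValueError("identity_threshold must be in (0, 100]")

    qlen = len(query)
    candidates = list(range(len(database)))
    # The prescreen only pays for itself on databases large enough that
    # k-mer set construction is cheaper than the distance screens it saves.
    if identity_threshold is not None and len(database) >= 50:
        d_max = _distance_bound(qlen, identity_threshold)
        # Pigeonhole: any alignment with <= d_max edits still shares an
        # exact k-mer as long as the windows outnumber the k-mers an edit
        # can destroy.  Only then is pruning lossless.
        if qlen - prescreen_kmer + 1 - prescreen_kmer * d_max >= 1:
            qkmers = _kmer_set(query, prescreen_kmer)
            if both_strands:
                qkmers |= _kmer_set(reverse_complement(query), prescreen_kmer)
            candidates = [
                i
                for i in candidates
                if not _kmer_set(database[i][1], prescreen_kmer).isdisjoint(qkmers)
            ]

    # Distance screen (cheap) to rank candidates, exact identity via the
    # alignment path only for the front-runners.
    scored: list[tuple[int, int]] = []  # (distance, index)
    for i in candidates:
        target = database[i][1]
        # Canonical ordering per pair: the shorter side is the edlib query
        # so terminal gaps on the longer side are free.
        q0, t0 = (query, target) if qlen <= len(target) else (target, query)
        k = (
            _distance_bound(len(q0), identity_threshold)
            if identity_threshold is not None
            else -1
        )
        ds = [_screen_distance(q0, t0, k)]
        if both_strands:
            ds.append(_screen_distance(reverse_complement(q0), t0, k))
        ds = [d for d in ds if d >= 0]
        if ds:
            scored.append((min(ds), i))
    if not scored:
        return None
    scored.sort(key=lambda x: (x[0], x[1]))

    best: DbHit | None = None
    best_dist = scored[0][0]
    for dist, i in scored:
        # Identity ranking can only disagree with distance ranking within
        # a small column-count margin; widening the front by the distance
        # bound below makes the exact-path pass conclusive.
        if best is not None and dist > best_dist + max(4, best_dist // 4):
            break
        hit_id, target = database[i]
        q0, t0 = (query, target) if qlen <= len(target) else (target, query)
        aln = _identity(q0, t0, both_strands)
        if best is None or aln.identity > best.alignment.identity + 1e-12:
            best = DbHit(hit_id, aln)
            best_dist = min(best_dist, dist)
    if best is None:
        return None
    if identity_threshold is not None and best.alignment.identity < identity_threshold:
        return None
    return best


class KmerIndex:
    """Inverted 12-mer index over a sequence set for lossless candidate
    pruning: a query can only reach ``threshold`` identity against records
    it shares at least ``L - k + 1 - k*d_max`` exact k-mers with (each of
    the at most d_max edits destroys at most k query k-mers)."""

    def __init__(self, database: Sequence[tuple[str, str]], k: int = 12):
        self.k = k
        self.database = database
        self.index: dict[int, list[int]] = {}
        for i, (_, seq) in enumerate(database):
            for km in _kmer_set(seq, k):
                self.index.setdefault(km, []).append(i)

    def candidates(self, query: str, identity_threshold: float) -> list[int]:
        from collections import Counter

        qk = _kmer_set(query, self.k) | _kmer_set(
            reverse_complement(query), self.k
        )
        counts: Counter = Counter()
        for km in qk:
            for i in self.index.get(km, ()):
                counts[i] += 1
        d_max = _distance_bound(len(query), identity_threshold)
        min_shared = max(1, len(query) - self.k + 1 - self.k * d_max)
        return sorted(i for i, c in counts.items() if c >= min_shared)


def db_search_exhaustive(
    query: str,
    database: Sequence[tuple[str, str]],
    identity_threshold: float | None = 97.0,
) -> DbHit | None:
    """Reference implementation: align against every record, no pruning."""
    if not database:
        raise EmptyDatabaseError("reference database is empty")
    best: DbHit | None = None
    for hit_id, target in database:
        aln = global_identity(query, target)
        if best is None or aln.identity > best.alignment.identity + 1e-12:
            best = DbHit(hit_id, aln)
    if best is None:
        return None
    if identity_threshold is not None and best.alignment.identity < identity_threshold:
        return None
    return best
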