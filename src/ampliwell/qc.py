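"""Ordered QC cascade applied to demultiplexed consensus reads.

Stage order (each stage only sees survivors of the previous one):

1. **Over-length removal** — reads longer than 1,600 nt are discarded;
   amplicons this long are themselves likely chimeric artifacts.
2. **Chimera removal** — a read is a chimera if some two-parent
   (bimeric) model explains it markedly better than any single
   reference: the best two-segment identity must beat the best
   single-parent identity by >= 2 percentage points and reach >= 97%.
3. **Nonspecific removal** — reads under 75% identity to every curated
   16S reference are off-target amplification products.
4. **Reliability filter** — a read is *reliable* if it is >= 97%
   identical to a curated reference (database hit) or, failing that, to
   any other read in the run (dataset hit).  The remainder are
   error-prone and discarded.  Unlike a coverage cutoff, this keeps
   low-coverage reads whose sequence is independently corroborated.

A coverage filter (>= 10x) is provided for comparison only; it is not
part of the default cascade.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .model import CCSRecord, FilterLedger, HIGH_COVERAGE_MIN, WellAddress
from .seqkernel import (
    DbHit,
    EmptyDatabaseError,
    KmerIndex,
    _kmer_set,
    _mask_n,
    db_search,
)

MAX_AMPLICON_LENGTH = 1600
NONSPECIFIC_MIN_IDENTITY = 75.0
RELIABILITY_THRESHOLD = 97.0
CHIMERA_GAIN_POINTS = 2.0
CHIMERA_MIN_IDENTITY = 97.0
CHIMERA_TOP_K = 4


@dataclass(frozen=True)
class ChimeraVerdict:
    ccs_id: str
    is_chimera: bool
    parent_a: str | None
    parent_b: str | None
    crossover: int
    chimera_score: float  # two-segment identity gain over best single parent


@dataclass(frozen=True)
class ReliabilityVerdict:
    ccs_id: str
    reliable: bool
    source: str  # database_hit | dataset_hit | none
    hit_id: str | None
    hit_identity: float


Bins = dict[WellAddress, list[CCSRecord]]


def _partition(
    bins: Bins, keep: dict[str, bool]
) -> tuple[Bins, list[CCSRecord]]:
    kept: Bins = {}
    dropped: list[CCSRecord] = []
    for well, reads in bins.items():
        for r in reads:
            if keep[r.ccs_id]:
                kept.setdefault(well, []).append(r)
            else:
                dropped.append(r)
    return kept, dropped


def length_filter(
    bins: Bins, max_length: int = MAX_AMPLICON_LENGTH
) -> tuple[Bins, list[CCSRecord]]:
    """Discard reads strictly longer than ``max_length`` (1,600 nt default)."""
    keep = {
        r.ccs_id: len(r.sequence) <= max_length
        for reads in bins.values()
        for r in reads
    }
    kept, dropped = _partition(bins, keep)
    dropped = [r.advance("discarded_length") for r in dropped]
    return kept, dropped


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _match_profile(read: str, parent: str) -> np.ndarray:
    """Boolean per-read-base vector: does this base match ``parent`` in the
    minimum-edit alignment?  Read bases deleted from the parent count as
    mismatches; parent insertions are ignored (read-coordinate profile)."""
    q, t = _mask_n(read.upper(), parent.upper())
    res = edlib.align(q, t, mode="HW", task="path")
    profile = np.zeros(len(read), dtype=bool)
    i = 0  # read coordinate
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        if op == "=":
            profile[i : i + n] = True
            i += n
        elif op in ("X", "M", "I"):
            i += n
        # 'D' consumes only the parent
    return profile


def _two_segment_from_profiles(
    pa: np.ndarray, pb: np.ndarray
) -> tuple[float, int]:
    n = pa.size
    prefix_a = np.concatenate([[0], np.cumsum(pa)])
    suffix_b = np.concatenate([np.cumsum(pb[::-1])[::-1], [0]])
    totals = prefix_a + suffix_b  # matches if crossover at each c in 0..n
    c = int(np.argmax(totals))
    return 100.0 * float(totals[c]) / n, c


def two_segment_identity(
    read: str, parent_a: str, parent_b: str
) -> tuple[float, int]:
    """Best identity of ``read`` explained as parent_a[:c] + parent_b[c:].

    Scans every crossover point using per-base match profiles; identity is
    scored over read coordinates (parent insertions ignored), a
    deliberate simplification that matches the single-parent profile
    scoring so identity gains are comparable.
    """
    return _two_segment_from_profiles(
        _match_profile(read, parent_a), _match_profile(read, parent_b)
    )


def _profile_identity(read: str, parent: str) -> float:
    return 100.0 * float(_match_profile(read, parent).sum()) / len(read)


def classify_chimera(
    read: CCSRecord,
    database: Sequence[tuple[str, str]],
    top_k: int = CHIMERA_TOP_K,
    gain_threshold: float = CHIMERA_GAIN_POINTS,
    min_identity: float = CHIMERA_MIN_IDENTITY,
    exhaustive: bool = False,
    _db_kmers: list[set[int]] | None = None,
) -> ChimeraVerdict:
    """Two-parent crossover chimera test against a chimera-free database.

    Candidate parents are the ``top_k`` references by shared 12-mers
    (all references when ``exhaustive``); every ordered parent pair and
    crossover point is scored from cached per-parent match profiles.
    """
    if not database:
        raise EmptyDatabaseError("chimera-free reference database is empty")
    seq = read.sequence
    if exhaustive or len(database) <= top_k:
        cand_idx = list(range(len(database)))
    else:
        if _db_kmers is None:
            _db_kmers = [_kmer_set(s, 12) for _, s in database]
        qk = _kmer_set(seq, 12)
        order = sorted(
            range(len(database)), key=lambda i: (len(qk & _db_kmers[i]), -i),
            reverse=True,
        )
        cand_idx = order[:top_k]

    profiles = {i: _match_profile(seq, database[i][1]) for i in cand_idx}
    i1 = max(
        100.0 * float(p.sum()) / len(seq) for p in profiles.values()
    )
    best_gain = -np.inf
    best = (None, None, -1, 0.0)
    for i in cand_idx:
        for j in cand_idx:
            if i == j:
                continue
            i2, cross = _two_segment_from_profiles(profiles[i], profiles[j])
            gain = i2 - i1
            if gain > best_gain:
                best_gain = gain
                best = (database[i][0], database[j][0], cross, i2)
    parent_a, parent_b, cross, i2 = best
    is_chimera = (
        parent_a is not None
        and best_gain >= gain_threshold
        and i2 >= min_identity
    )
    if not is_chimera:
        return ChimeraVerdict(read.ccs_id, False, None, None, -1, float(best_gain))
    return ChimeraVerdict(read.ccs_id, True, parent_a, parent_b, cross, float(best_gain))


def chimera_filter(
    bins: Bins,
    chimera_free_db: Sequence[tuple[str, str]],
    top_k: int = CHIMERA_TOP_K,
    gain_threshold: float = CHIMERA_GAIN_POINTS,
) -> tuple[Bins, list[CCSRecord], list[ChimeraVerdict]]:
    db_kmers = [_kmer_set(s, 12) for _, s in chimera_free_db]
    verdicts: list[ChimeraVerdict] = []
    keep: dict[str, bool] = {}
    for reads in bins.values():
        for r in reads:
            v = classify_chimera(
                r, chimera_free_db, top_k, gain_threshold, _db_kmers=db_kmers
            )
            verdicts.append(v)
            keep[r.ccs_id] = not v.is_chimera
    kept, dropped = _partition(bins, keep)
    dropped = [r.advance("discarded_chimera") for r in dropped]
    return kept, dropped, verdicts


def nonspecific_filter(
    bins: Bins,
    curated_db: Sequence[tuple[str, str]],
    min_identity: float = NONSPECIFIC_MIN_IDENTITY,
) -> tuple[Bins, list[CCSRecord]]:
    """Discard reads with no hit or best identity strictly below 75%."""
    if not curated_db:
        raise EmptyDatabaseError("curated database is empty")
    keep: dict[str, bool] = {}
    for reads in bins.values():
        for r in reads:
            hit = db_search(
                r.sequence, curated_db, identity_threshold=min_identity,
                both_strands=True,
            )
            keep[r.ccs_id] = hit is not None
    kept, dropped = _partition(bins, keep)
    dropped = [r.advance("discarded_nonspecific") for r in dropped]
    return kept, dropped


def reliability_filter(
    bins: Bins,
    curated_db: Sequence[tuple[str, str]],
    threshold: float = RELIABILITY_THRESHOLD,
) -> tuple[Bins, list[CCSRecord], list[ReliabilityVerdict]]:
    """Two-stage reliability test.

    Stage 1: >= ``threshold``% identity to a curated reference.
    Stage 2 (stage-1 misses only): >= ``threshold``% identity to any
    *other* read in the run (self excluded).  Reads failing both are
    error-prone and discarded.
    """
    if not curated_db:
        raise EmptyDatabaseError("curated database is empty")
    all_reads = [r for reads in bins.values() for r in reads]
    verdicts: dict[str, ReliabilityVerdict] = {}
    misses: list[CCSRecord] = []
    for r in all_reads:
        hit = db_search(
            r.sequence, curated_db, identity_threshold=threshold, both_strands=True
        )
        if hit is not None:
            verdicts[r.ccs_id] = ReliabilityVerdict(
                r.ccs_id, True, "database_hit", hit.hit_id, hit.alignment.identity
            )
        else:
            misses.append(r)
    dataset = [(r.ccs_id, r.sequence) for r in all_reads]
    index = KmerIndex(dataset) if misses else None
    for r in misses:
        cand = index.candidates(r.sequence, threshold)
        others = [dataset[i] for i in cand if dataset[i][0] != r.ccs_id]
        hit: DbHit | None = None
        if others:
            hit = db_search(r.sequence, others, identity_threshold=threshold)
        if hit is not None:
            verdicts[r.ccs_id] = ReliabilityVerdict(
                r.ccs_id, True, "dataset_hit", hit.hit_id, hit.alignment.identity
            )
        else:
            verdicts[r.ccs_id] = ReliabilityVerdict(r.ccs_id, False, "none", None, 0.0)
    keep = {cid: v.reliable for cid, v in verdicts.items()}
    kept: Bins = {}
    dropped: list[CCSRecord] = []
    for well, reads in bins.items():
        for r in reads:
            if keep[r.ccs_id]:
                kept.setdefault(well, []).append(
                    r.advance("usable", reliability_source=verdicts[r.ccs_id].source)
                )
            else:
                dropped.append(r.advance("error_prone"))
    return kept, dropped, list(verdicts.values())


def coverage_filter(
    bins: Bins, min_coverage: int = HIGH_COVERAGE_MIN
) -> tuple[Bins, list[CCSRecord]]:
    """Conventional coverage cutoff (>= 10x), for comparison reports only."""
    keep = {
        r.ccs_id: r.coverage >= min_coverage
        for reads in bins.values()
        for r in reads
    }
    return _partition(bins, keep)


def _wells_with_reads(bins: Bins) -> int:
    return sum(1 for reads in bins.values() if reads)


@dataclass
class QCResult:
    usable: Bins
    ledger: FilterLedger
    chimera_verdicts: list[ChimeraVerdict]
    reliability_verdicts: list[ReliabilityVerdict]
    discarded: dict[str, list[CCSRecord]]


def run_qc(
    bins: Bins,
    chimera_free_db: Sequence[tuple[str, str]],
    curated_db: Sequence[tuple[str, str]],
    ledger: FilterLedger | None = None,
    max_length: int = MAX_AMPLICON_LENGTH,
    nonspecific_min_identity: float = NONSPECIFIC_MIN_IDENTITY,
    reliability_threshold: float = RELIABILITY_THRESHOLD,
    chimera_top_k: int = CHIMERA_TOP_K,
    chimera_gain: float = CHIMERA_GAIN_POINTS,
) -> QCResult:
    """Length -> chimera -> nonspecific -> reliability, with full accounting."""
    ledger = ledger or FilterLedger(
        assembled=sum(len(v) for v in bins.values()),
        demultiplexed=sum(len(v) for v in bins.values()),
    )
    bins1, over = length_filter(bins, max_length)
    ledger.over_length = len(over)
    bins2, chim, chim_verdicts = chimera_filter(
        bins1, chimera_free_db, chimera_top_k, chimera_gain
    )
    ledger.chimeric = len(chim)
    bins3, nonspec = nonspecific_filter(bins2, curated_db, nonspecific_min_identity)
    ledger.nonspecific = len(nonspec)
    ledger.usable_pre_filter = sum(len(v) for v in bins3.values())
    ledger.wells_recovered_pre = _wells_with_reads(bins3)

    cov_bins, _ = coverage_filter(bins3)
    ledger.usable_cov_ge10 = sum(len(v) for v in cov_bins.values())
    ledger.wells_recovered_cov = _wells_with_reads(cov_bins)

    usable, error_prone, rel_verdicts = reliability_filter(
        bins3, curated_db, reliability_threshold
    )
    ledger.usable_reliable = sum(len(v) for v in usable.values())
    ledger.reliable_db_hits = sum(
        1 for v in rel_verdicts if v.source == "database_hit"
    )
    ledger.reliable_dataset_hits = sum(
        1 for v in rel_verdicts if v.source == "dataset_hit"
    )
    ledger.error_prone = len(error_prone)
    ledger.wells_recovered_reliable = _wells_with_reads(usable)
    return QCResult(
        usable,
        ledger,
        chim_verdicts,
        rel_verdicts,
        {
            "over_length": over,
            "chimeric": chim,
            "nonspecific": nonspec,
            "error_prone": error_prone,
        },
    )
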