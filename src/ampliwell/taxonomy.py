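"""Naive-Bayes k-mer taxonomy classification with bootstrap confidence.

A word-presence (Bernoulli) naive-Bayes model over 8-mers is trained per
genus from a reference FASTA plus a rank-delimited lineage table.  A
query is assigned the genus maximising the summed log word probabilities;
confidence is the fraction of 100 bootstrap subsamples (⌊L/k⌋ words drawn
with replacement) that agree with the full-data call, propagated to
higher ranks by summing votes of genera within each taxon.  A genus is
*reported* only when its confidence exceeds 0.95.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .simulate import RANKS

WORD_SIZE = 8
N_BOOTSTRAP = 100
GENUS_CONFIDENCE_THRESHOLD = 0.95
MIN_QUERY_WORDS_FACTOR = 8  # query must be >= 8*k nt

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class TrainingError(ValueError):
    pass


@dataclass
class TaxAssignment:
    query_id: str
    per_rank: dict[str, tuple[str, float]]  # rank -> (label, confidence)
    reported_genus: str | None

    @property
    def genus_confidence(self) -> float:
        return self.per_rank["genus"][1] if "genus" in self.per_rank else 0.0


def _words(seq: str, k: int) -> np.ndarray:
    """Codes of all overlapping k-mers containing only A/C/G/T."""
    seq = seq.upper()
    arr = np.full(len(seq), -1, dtype=np.int64)
    for b, c in _BASE_CODE.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = c
    if arr.size < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (windows >= 0).all(axis=1)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return (windows[valid] * weights).sum(axis=1)


@dataclass
class TrainedClassifier:
    k: int
    genera: list[str]
    log_prob: np.ndarray  # (4^k, n_genera) log word probabilities
    log_background: np.ndarray  # (4^k,) log word prior — the null class
    lineage_by_genus: dict[str, dict[str, str]]  # genus -> rank -> label

    @property
    def n_genera(self) -> int:
        return len(self.genera)


def parse_lineage(lineage: str) -> dict[str, str]:
    parts = [p.strip() for p in lineage.split(";")]
    if len(parts) != len(RANKS):
        raise TrainingError(
            f"lineage must have {len(RANKS)} ranks ({';'.join(RANKS)}): {lineage!r}"
        )
    return dict(zip(RANKS, parts))


def train(
    sequences: dict[str, str],
    lineages: dict[str, str],
    k: int = WORD_SIZE,
) -> TrainedClassifier:
    """Train genus-conditional word-presence probabilities.

    ``p(w|g) = (m_wg + P_w) / (n_g + 1)`` with word prior
    ``P_w = (n_w + 0.5) / (N + 1)`` — the classic smoothed estimator for
    this classifier family.
    """
    missing = set(sequences) - set(lineages)
    if missing:
        raise TrainingError(f"sequences without lineage: {sorted(missing)[:5]}")
    genus_of: dict[str, str] = {}
    lineage_by_genus: dict[str, dict[str, str]] = {}
    for sid in sequences:
        ranks = parse_lineage(lineages[sid])
        genus_of[sid] = ranks["genus"]
        lineage_by_genus[ranks["genus"]] = ranks
    genera = sorted(lineage_by_genus)
    if len(genera) < 2:
        raise TrainingError("training requires at least 2 genera")

    n_words = 4**k
    n_total = np.zeros(n_words)  # sequences containing each word
    m = np.zeros((n_words, len(genera)))  # per-genus containment counts
    n_g = np.zeros(len(genera))
    gidx = {g: i for i, g in enumerate(genera)}
    for sid, seq in sequences.items():
        present = np.unique(_words(seq, k))
        g = gidx[genus_of[sid]]
        n_total[present] += 1
        m[present, g] += 1
        n_g[g] += 1
    prior = (n_total + 0.5) / (len(sequences) + 1.0)
    prob = (m + prior[:, None]) / (n_g[None, :] + 1.0)
    # The prior doubles as a background (null) class: a query must beat
    # it before any genus vote counts, which keeps chance k-mer matches
    # on unrelated sequences from accumulating into a confident call.
    return TrainedClassifier(k, genera, np.log(prob), np.log(prior), lineage_by_genus)


def train_from_files(
    fasta_path: str | Path, lineage_path: str | Path, k: int = WORD_SIZE
) -> TrainedClassifier:
    seqs = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    df = pd.read_csv(lineage_path, sep="\t", dtype=str)
    lineages = dict(zip(df["taxon_id"], df["lineage"]))
    return train(seqs, lineages, k)


def _score(words: np.ndarray, clf: TrainedClassifier) -> np.ndarray:
    return clf.log_prob[words].sum(axis=0)


def classify(
    query_id: str,
    sequence: str,
    clf: TrainedClassifier,
    n_bootstrap: int = N_BOOTSTRAP,
    seed: int = 0,
) -> TaxAssignment:
    """Assign a genus with bootstrap confidence, propagated up ranks.

    Queries shorter than ``8 * k`` nt are unassigned at zero confidence.
    The bootstrap generator is seeded from ``seed`` and a CRC of the
    sequence, so results are reproducible and independent of call order.
    """
    words = _words(sequence, clf.k)
    if len(sequence) < MIN_QUERY_WORDS_FACTOR * clf.k or words.size == 0:
        return TaxAssignment(query_id, {r: ("unassigned", 0.0) for r in RANKS}, None)
    full_call = int(np.argmax(_score(np.unique(words), clf)))

    rng = np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(sequence.encode())])
    )
    m = max(1, len(sequence) // clf.k)
    idx = rng.integers(0, words.size, size=(n_bootstrap, m))
    votes = np.zeros(clf.n_genera)
    for b in range(n_bootstrap):
        sample = words[idx[b]]
        scores = _score(sample, clf)
        # a vote counts only when the best genus beats the background
        if scores.max() > clf.log_background[sample].sum():
            votes[int(np.argmax(scores))] += 1
    votes /= n_bootstrap

    per_rank: dict[str, tuple[str, float]] = {}
    full_lineage = clf.lineage_by_genus[clf.genera[full_call]]
    for rank in RANKS:
        label = full_lineage[rank]
        conf = sum(
            votes[i]
            for i, g in enumerate(clf.genera)
            if clf.lineage_by_genus[g][rank] == label
        )
        per_rank[rank] = (label, float(conf))
    genus_label, genus_conf = per_rank["genus"]
    reported = genus_label if genus_conf > GENUS_CONFIDENCE_THRESHOLD else None
    return TaxAssignment(query_id, per_rank, reported)


def classify_otus(
    otus,
    clf: TrainedClassifier,
    n_bootstrap: int = N_BOOTSTRAP,
    seed: int = 0,
) -> pd.DataFrame:
    """Taxonomy table for a list of OTUs (classifies each centroid)."""
    rows = []
    for otu in otus:
        a = classify(otu.otu_id, otu.centroid_seq, clf, n_bootstrap, seed)
        lineage = ";".join(a.per_rank[r][0] for r in RANKS)
        row = dict(otu_id=otu.otu_id, lineage=lineage,
                   reported_genus=a.reported_genus or "unassigned")
        for r in RANKS:
            row[f"conf_{r}"] = a.per_rank[r][1]
        rows.append(row)
    cols = ["otu_id", "lineage", "reported_genus"] + [f"conf_{r}" for r in RANKS]
    return pd.DataFrame(rows, columns=cols)
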