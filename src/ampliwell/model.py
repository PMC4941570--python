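"""Core data model for a multiplexed culture-collection sequencing run.

A run multiplexes several 96-well plates into one tube: every amplicon
carries a 9-bp plate barcode, an 8-bp row barcode (rows A-H) and an 8-bp
column barcode (columns 1-12), each sitting at a fixed offset from a
constant anchor oligo (forward transposase 14 nt, reverse transposase
15 nt, universal reverse primer 16 nt).  This module defines the barcode
manifest and its validation, well addressing, the consensus-read (CCS)
record with its coverage arithmetic, and the stage-by-stage filter ledger
that accounts for every read through the QC cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

ROWS = "ABCDEFGH"
COLUMNS = list(range(1, 13))

# Reserved control addresses: H10 positive control, H11/H12 negative.
POSITIVE_CONTROL_WELLS = frozenset({("H", 10)})
NEGATIVE_CONTROL_WELLS = frozenset({("H", 11), ("H", 12)})
CONTROL_WELLS = POSITIVE_CONTROL_WELLS | NEGATIVE_CONTROL_WELLS

PLATE_BARCODE_LEN = 9
ROW_BARCODE_LEN = 8
COLUMN_BARCODE_LEN = 8
ANCHOR_LENGTHS = {
    "fwd_transposase": 14,
    "rev_transposase": 15,
    "univ_reverse_primer": 16,
}

# Public Nextera transposase sequences and a non-degenerate 16-nt suffix
# of the 1492r universal reverse primer.
DEFAULT_ANCHORS = {
    "fwd_transposase": "TCGTCGGCAGCGTC",
    "rev_transposase": "GTCTCGTGGGCTCGG",
    "univ_reverse_primer": "TACCTTGTTACGACTT",
}

# Coverage below which a consensus read is never admitted into a run.
MIN_ADMITTED_COVERAGE = 2
# Boundary between the low- and high-coverage accuracy classes.
HIGH_COVERAGE_MIN = 10

STATUSES = (
    "raw",
    "demultiplexed",
    "discarded_length",
    "discarded_chimera",
    "discarded_nonspecific",
    "error_prone",
    "usable",
)


class ManifestError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class WellAddress:
    """(plate, row A-H, column 1-12) position in a 96-well plate."""

    plate_id: str
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise ValueError(f"row must be one of {ROWS}, got {self.row!r}")
        if self.column not in COLUMNS:
            raise ValueError(f"column must be in 1..12, got {self.column}")

    @property
    def label(self) -> str:
        return f"{self.row}{self.column}"

    @property
    def is_positive_control(self) -> bool:
        return (self.row, self.column) in POSITIVE_CONTROL_WELLS

    @property
    def is_negative_control(self) -> bool:
        return (self.row, self.column) in NEGATIVE_CONTROL_WELLS

    @property
    def is_control(self) -> bool:
        return (self.row, self.column) in CONTROL_WELLS


@dataclass(frozen=True)
class ConstructLayout:
    """Relative placement of each barcode class in the amplicon construct.

    Plus-strand order:
    ``[row bc][fwd transposase][16S insert][universal reverse primer]``
    ``[plate bc][rev transposase][column bc]``.

    Offsets give the barcode start relative to its flanking anchor:
    negative = upstream of the anchor start, positive = downstream of the
    anchor end.
    """

    row_anchor: str = "fwd_transposase"
    row_offset: int = -ROW_BARCODE_LEN  # immediately upstream
    plate_anchor: str = "univ_reverse_primer"
    plate_offset: int = 0  # immediately downstream
    column_anchor: str = "rev_transposase"
    column_offset: int = 0

    def barcode_len(self, klass: str) -> int:
        return {
            "plate": PLATE_BARCODE_LEN,
            "row": ROW_BARCODE_LEN,
            "column": COLUMN_BARCODE_LEN,
        }[klass]


@dataclass
class BarcodeManifest:
    """Plate/row/column barcode tables plus anchors and construct layout."""

    plate_barcodes: dict[str, str]
    row_barcodes: dict[str, str]
    column_barcodes: dict[int, str]
    anchors: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ANCHORS))
    layout: ConstructLayout = field(default_factory=ConstructLayout)

    @property
    def n_plates(self) -> int:
        return len(self.plate_barcodes)

    def overhead_length(self) -> int:
        """Construct length minus insert length."""
        return (
            ROW_BARCODE_LEN
            + PLATE_BARCODE_LEN
            + COLUMN_BARCODE_LEN
            + sum(ANCHOR_LENGTHS.values())
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for pid, seq in self.plate_barcodes.items():
            rows.append(("plate", pid, seq))
        for rid, seq in self.row_barcodes.items():
            rows.append(("row", rid, seq))
        for cid, seq in self.column_barcodes.items():
            rows.append(("column", str(cid), seq))
        for aid, seq in self.anchors.items():
            rows.append(("anchor", aid, seq))
        pd.DataFrame(rows, columns=["class", "id", "sequence"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeManifest":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except OSError as exc:
            raise ManifestError(f"cannot read manifest: {exc}") from exc
        required = {"class", "id", "sequence"}
        if not required.issubset(df.columns):
            raise ManifestError(f"manifest must have columns {sorted(required)}")
        plates, rows, cols, anchors = {}, {}, {}, {}
        for _, rec in df.iterrows():
            klass, ident, seq = rec["class"], rec["id"], rec["sequence"].upper()
            if klass == "plate":
                plates[ident] = seq
            elif klass == "row":
                rows[ident] = seq
            elif klass == "column":
                cols[int(ident)] = seq
            elif klass == "anchor":
                anchors[ident] = seq
            else:
                raise ManifestError(f"unknown barcode class {klass!r}")
        return cls(plates, rows, cols, anchors or dict(DEFAULT_ANCHORS))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def validate_manifest(manifest: BarcodeManifest, min_distance: int = 2) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    violations: list[str] = []
    classes = [
        ("plate", manifest.plate_barcodes, PLATE_BARCODE_LEN),
        ("row", manifest.row_barcodes, ROW_BARCODE_LEN),
        ("column", manifest.column_barcodes, COLUMN_BARCODE_LEN),
    ]
    for name, table, expected_len in classes:
        for ident, seq in table.items():
            if len(seq) != expected_len:
                violations.append(
                    f"{name} barcode {ident}: length {len(seq)} != {expected_len}"
                )
        idents = list(table)
        for i, a in enumerate(idents):
            for b in idents[i + 1 :]:
                sa, sb = table[a], table[b]
                if len(sa) != len(sb):
                    continue  # already reported as a length violation
                d = hamming(sa, sb)
                if d == 0:
                    violations.append(f"{name} barcodes {a} and {b} are identical")
                elif d < min_distance:
                    violations.append(
                        f"{name} barcodes {a} and {b}: Hamming distance "
                        f"{d} < {min_distance}"
                    )
    for aid, expected_len in ANCHOR_LENGTHS.items():
        seq = manifest.anchors.get(aid)
        if seq is None:
            violations.append(f"anchor {aid} missing")
        elif len(seq) != expected_len:
            violations.append(
                f"anchor {aid}: length {len(seq)} != {expected_len}"
            )
    return violations


def _generate_barcode_set(
    n: int, length: int, rng: np.random.Generator, existing: list[str], min_dist: int = 3
) -> list[str]:
    bases = "ACGT"
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100_000:
            raise ManifestError("could not generate a distance-checked barcode set")
        cand = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        if all(
            hamming(cand, other) >= min_dist
            for other in out + [e for e in existing if len(e) == length]
        ):
            out.append(cand)
    return out


def default_manifest(n_plates: int = 5) -> BarcodeManifest:
    """Deterministic bundled manifest with distance-checked barcodes.

    Barcodes are generated once from a fixed generator (independent of any
    run seed — the manifest is experimental design, not data) with pairwise
    Hamming distance >= 3 within each class.
    """
    rng = np.random.default_rng(29543)
    plate = _generate_barcode_set(n_plates, PLATE_BARCODE_LEN, rng, [])
    row = _generate_barcode_set(8, ROW_BARCODE_LEN, rng, [])
    col = _generate_barcode_set(12, COLUMN_BARCODE_LEN, rng, row)
    return BarcodeManifest(
        plate_barcodes={f"P{i + 1}": s for i, s in enumerate(plate)},
        row_barcodes=dict(zip(ROWS, row)),
        column_barcodes=dict(zip(COLUMNS, col)),
    )


def compute_ccs_coverage(subread_total_nt: int, ccs_length: int) -> int:
    """Coverage = round(total subread nucleotides / consensus length).

    Rounded to the nearest integer, ties half away from zero.
    """
    if subread_total_nt <= 0 or ccs_length <= 0:
        raise ValueError("subread total and CCS length must be positive")
    return int(math.floor(subread_total_nt / ccs_length + 0.5))


def coverage_class(coverage: int) -> str:
    """Accuracy class of a consensus read: ``low`` (<10x) or ``high`` (>=10x)."""
    if coverage < MIN_ADMITTED_COVERAGE:
        raise ValueError(
            f"coverage {coverage} below the {MIN_ADMITTED_COVERAGE}x admission minimum"
        )
    return "high" if coverage >= HIGH_COVERAGE_MIN else "low"


def expected_well_count(manifest: BarcodeManifest, n_plates: int | None = None) -> int:
    """Total addressable wells = plates x rows x columns."""
    if n_plates is None:
        n_plates = manifest.n_plates
    return n_plates * len(manifest.row_barcodes) * len(manifest.column_barcodes)


@dataclass
class CCSRecord:
    """One circular-consensus read moving through the pipeline."""

    ccs_id: str
    sequence: str
    subread_total_nt: int
    coverage: int = 0
    well: WellAddress | None = None
    status: str = "raw"
    reliability_source: str = "none"  # none | database_hit | dataset_hit

    def __post_init__(self) -> None:
        if self.coverage == 0 and self.subread_total_nt > 0 and self.sequence:
            self.coverage = compute_ccs_coverage(
                self.subread_total_nt, len(self.sequence)
            )

    @property
    def coverage_class(self) -> str:
        return coverage_class(self.coverage)

    def advance(self, status: str, **kwargs) -> "CCSRecord":
        """Forward-only status transition along the cascade."""
        order = {s: i for i, s in enumerate(STATUSES)}
        if status not in order:
            raise ValueError(f"unknown status {status!r}")
        if order[status] < order[self.status] and status != "usable":
            raise ValueError(f"cannot move {self.ccs_id} from {self.status} to {status}")
        return replace(self, status=status, **kwargs)


# Row labels mirror the published run-accounting table verbatim so ledger
# reports diff cleanly against it.
LEDGER_LABELS = {
    "assembled": "Total number of assembled CCSs (≥2× coverage)",
    "demultiplexed": "Demultiplexed CCSs",
    "non_demultiplexed": "Non-demultiplexed CCSs",
    "over_length": "CCSs larger than expected (>1,600 bp)",
    "chimeric": "Chimeric CCSs",
    "nonspecific": "Non-specific sequences",
    "usable_pre_filter": "Usable CCSs before quality filtering",
    "wells_recovered_pre": "Recovered wells before quality filtering",
    "usable_cov_ge10": "Usable CCSs after filtering by coverage (≥10× coverage)",
    "wells_recovered_cov": "Recovered wells after filtering by coverage (≥10× coverage)",
    "usable_reliable": "Usable CCSs after filtering by reliability",
    "reliable_db_hits": "CCSs with hits against reference database",
    "reliable_dataset_hits": "CCSs with no hits against reference database and with hit against CCS dataset",
    "error_prone": "Error-prone CCSs",
    "wells_recovered_reliable": "Recovered wells after filtering by reliability",
}


@dataclass
class FilterLedger:
    """Per-stage read accounting for one run.

    Conservation identities (checked by :meth:`violations`):

    * ``assembled = demultiplexed + non_demultiplexed``
    * ``usable_reliable = reliable_db_hits + reliable_dataset_hits``
    * ``usable_pre_filter = usable_reliable + error_prone``
    """

    assembled: int = 0
    demultiplexed: int = 0
    non_demultiplexed: int = 0
    over_length: int = 0
    chimeric: int = 0
    nonspecific: int = 0
    usable_pre_filter: int = 0
    wells_recovered_pre: int = 0
    usable_cov_ge10: int = 0
    wells_recovered_cov: int = 0
    usable_reliable: int = 0
    reliable_db_hits: int = 0
    reliable_dataset_hits: int = 0
    error_prone: int = 0
    wells_recovered_reliable: int = 0

    def violations(self) -> list[str]:
        out = []
        if self.assembled != self.demultiplexed + self.non_demultiplexed:
            out.append("assembled != demultiplexed + non_demultiplexed")
        if self.usable_reliable != self.reliable_db_hits + self.reliable_dataset_hits:
            out.append("usable_reliable != reliable_db_hits + reliable_dataset_hits")
        if self.usable_pre_filter != self.usable_reliable + self.error_prone:
            out.append("usable_pre_filter != usable_reliable + error_prone")
        return out

    # -- derived quantities (also recomputable from a printed table) --

    def chimera_fraction_pct(self) -> float:
        """Chimeric reads as % of demultiplexed reads."""
        return 100.0 * self.chimeric / self.demultiplexed

    def nonspecific_fraction_pct(self) -> float:
        return 100.0 * self.nonspecific / self.demultiplexed

    def well_recovery_pct(self, expected_wells: int) -> float:
        return 100.0 * self.wells_recovered_reliable / expected_wells

    def high_coverage_usable_pct(self) -> float:
        """Coverage-filter survivors as % of pre-filter usable reads."""
        return 100.0 * self.usable_cov_ge10 / self.usable_pre_filter

    def __add__(self, other: "FilterLedger") -> "FilterLedger":
        kwargs = {
            f: getattr(self, f) + getattr(other, f)
            for f in self.__dataclass_fields__
        }
        return FilterLedger(**kwargs)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(LEDGER_LABELS[f], getattr(self, f)) for f in LEDGER_LABELS]
        pd.DataFrame(rows, columns=["stage", "count"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FilterLedger":
        df = pd.read_csv(path, sep="\t")
        label_to_field = {v: k for k, v in LEDGER_LABELS.items()}
        counts = {
            label_to_field[row["stage"]]: int(row["count"])
            for _, row in df.iterrows()
            if row["stage"] in label_to_field
        }
        return cls.from_counts(counts)

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "FilterLedger":
        known = set(cls.__dataclass_fields__)
        unknown = set(counts) - known
        if unknown:
            raise ValueError(f"unknown ledger fields: {sorted(unknown)}")
        return cls(**counts)


def read_subread_sidecar(path: str | Path) -> dict[str, int]:
    """Read the (ccs_id, subread_total_nt) TSV sidecar."""
    df = pd.read_csv(path, sep="\t", dtype={"ccs_id": str, "subread_total_nt": int})
    return dict(zip(df["ccs_id"], df["subread_total_nt"]))
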