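"""Combinatorial barcode demultiplexing of consensus reads.

Each read is assigned to a (plate, row, column) well by: (1) locating the
three constant anchor oligos on either strand with up to 3 mismatches,
(2) predicting each barcode's position from its flanking anchor via the
construct layout, and (3) requiring an exact (0-mismatch) barcode match
at the predicted position.  A read with any barcode class uncalled or
positionally inconsistent is left unassigned — the stringent exact-match
rule trades yield for traceability: an assigned read is wrong only if a
full 8-9 nt barcode mutates into another valid barcode, which the
manifest's Hamming-distance checks make astronomically unlikely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import (
    ANCHOR_LENGTHS,
    BarcodeManifest,
    CCSRecord,
    COLUMN_BARCODE_LEN,
    FilterLedger,
    PLATE_BARCODE_LEN,
    ROW_BARCODE_LEN,
    WellAddress,
)
from .seqkernel import OligoHit, oligo_search, reverse_complement

MAX_ANCHOR_MISMATCHES = 3
POSITION_TOLERANCE = 4  # nt around the predicted barcode start

BARCODE_CLASSES = ("plate", "row", "column")


@dataclass
class BarcodeCall:
    called_id: str | None
    observed: str | None
    position: int | None
    position_consistent: bool


@dataclass
class DemuxResult:
    ccs_id: str
    well: WellAddress | None
    strand: str  # strand of the input read relative to construct plus
    anchor_hits: dict[str, OligoHit | None]
    barcode_calls: dict[str, BarcodeCall] = field(default_factory=dict)
    insert_span: tuple[int, int] | None = None  # on the oriented read

    @property
    def assigned(self) -> bool:
        return self.well is not None


def locate_anchors(
    sequence: str, manifest: BarcodeManifest, max_mismatches: int = MAX_ANCHOR_MISMATCHES
) -> tuple[dict[str, OligoHit | None], str]:
    """Best hit per anchor and the read's strand.

    Both orientations are scanned; the strand on which more anchors are
    found wins (tie -> plus).  Per anchor the best hit is fewest
    mismatches, then leftmost.
    """
    per_strand: dict[str, dict[str, OligoHit | None]] = {}
    for strand, seq in (("plus", sequence), ("minus", reverse_complement(sequence))):
        hits: dict[str, OligoHit | None] = {}
        for name, oligo in manifest.anchors.items():
            found = oligo_search(seq, oligo, max_mismatches, strands="plus")
            hits[name] = found[0] if found else None
        per_strand[strand] = hits
    n_plus = sum(h is not None for h in per_strand["plus"].values())
    n_minus = sum(h is not None for h in per_strand["minus"].values())
    strand = "minus" if n_minus > n_plus else "plus"
    return per_strand[strand], strand


def _expected_positions(read_len: int, manifest: BarcodeManifest) -> dict[str, int]:
    """Construct-coordinate starts for anchors and barcodes, given the
    read length (insert length = read length − fixed overhead)."""
    n = read_len
    la = ANCHOR_LENGTHS
    return {
        "row": 0,
        "fwd_transposase": ROW_BARCODE_LEN,
        "univ_reverse_primer": n
        - COLUMN_BARCODE_LEN
        - la["rev_transposase"]
        - PLATE_BARCODE_LEN
        - la["univ_reverse_primer"],
        "plate": n - COLUMN_BARCODE_LEN - la["rev_transposase"] - PLATE_BARCODE_LEN,
        "rev_transposase": n - COLUMN_BARCODE_LEN - la["rev_transposase"],
        "column": n - COLUMN_BARCODE_LEN,
    }


def predict_barcode_positions(
    anchor_hits: dict[str, OligoHit | None],
    manifest: BarcodeManifest,
    read_len: int,
) -> dict[str, int | None]:
    """Predicted start of each barcode class on the oriented read.

    A class flanked by a found anchor abuts it exactly (indel-immune); a
    class whose own anchor is missing falls back to the construct's global
    coordinates shifted by the nearest found anchor.
    """
    layout = manifest.layout
    flank = {
        "row": (layout.row_anchor, layout.row_offset, "start"),
        "plate": (layout.plate_anchor, layout.plate_offset, "end"),
        "column": (layout.column_anchor, layout.column_offset, "end"),
    }
    expected = _expected_positions(read_len, manifest)
    found = {a: h for a, h in anchor_hits.items() if h is not None}
    out: dict[str, int | None] = {}
    for klass, (anchor, offset, side) in flank.items():
        hit = anchor_hits.get(anchor)
        if hit is not None:
            ref = hit.start if side == "start" else hit.end
            out[klass] = ref + offset
        elif found:
            # Global fallback: shift expected coordinates by the observed
            # drift of the anchor closest to this barcode class.
            nearest = min(
                found,
                key=lambda a: abs(expected[a] - expected[klass]),
            )
            shift = found[nearest].start - expected[nearest]
            out[klass] = expected[klass] + shift
        else:
            out[klass] = None
    return out


def _class_table(manifest: BarcodeManifest, klass: str) -> dict[str, str]:
    if klass == "plate":
        return manifest.plate_barcodes
    if klass == "row":
        return manifest.row_barcodes
    return {str(k): v for k, v in manifest.column_barcodes.items()}


def _exact_matches(seq: str, barcode: str) -> list[int]:
    out, start = [], 0
    while True:
        i = seq.find(barcode, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def call_barcodes(
    sequence: str,
    predicted: dict[str, int | None],
    manifest: BarcodeManifest,
    tolerance: int = POSITION_TOLERANCE,
) -> dict[str, BarcodeCall]:
    """Exact-match barcode calling at the predicted positions.

    The whole oriented read is scanned for exact matches to every barcode
    of a class; the call is the match closest to the predicted start and
    is position-consistent iff it lies within ``tolerance``.  Two distinct
    barcode ids matching inside the window is ambiguous -> no call.
    """
    calls: dict[str, BarcodeCall] = {}
    for klass in BARCODE_CLASSES:
        pred = predicted.get(klass)
        if pred is None:
            calls[klass] = BarcodeCall(None, None, None, False)
            continue
        matches: list[tuple[str, int]] = []
        for ident, barcode in _class_table(manifest, klass).items():
            for pos in _exact_matches(sequence, barcode):
                matches.append((ident, pos))
        if not matches:
            calls[klass] = BarcodeCall(None, None, None, False)
            continue
        in_window = [(i, p) for i, p in matches if abs(p - pred) <= tolerance]
        if len({i for i, _ in in_window}) > 1:
            calls[klass] = BarcodeCall(None, None, None, False)  # ambiguous
            continue
        if in_window:
            ident, pos = min(in_window, key=lambda m: abs(m[1] - pred))
            blen = manifest.layout.barcode_len(klass)
            calls[klass] = BarcodeCall(ident, sequence[pos : pos + blen], pos, True)
        else:
            ident, pos = min(matches, key=lambda m: abs(m[1] - pred))
            blen = manifest.layout.barcode_len(klass)
            calls[klass] = BarcodeCall(ident, sequence[pos : pos + blen], pos, False)
    return calls


def demultiplex_read(
    ccs: CCSRecord,
    manifest: BarcodeManifest,
    tolerance: int = POSITION_TOLERANCE,
    max_anchor_mismatches: int = MAX_ANCHOR_MISMATCHES,
) -> DemuxResult:
    anchor_hits, strand = locate_anchors(ccs.sequence, manifest, max_anchor_mismatches)
    oriented = (
        ccs.sequence if strand == "plus" else reverse_complement(ccs.sequence)
    )
    predicted = predict_barcode_positions(anchor_hits, manifest, len(oriented))
    calls = call_barcodes(oriented, predicted, manifest, tolerance)
    well = None
    if all(c.called_id is not None and c.position_consistent for c in calls.values()):
        well = WellAddress(
            calls["plate"].called_id,
            calls["row"].called_id,
            int(calls["column"].called_id),
        )
    span = insert_span(len(oriented), anchor_hits, predicted)
    return DemuxResult(ccs.ccs_id, well, strand, anchor_hits, calls, span)


def insert_span(
    read_len: int,
    anchor_hits: dict[str, OligoHit | None],
    predicted: dict[str, int | None],
) -> tuple[int, int] | None:
    """Locate the 16S insert on the oriented read.

    The insert runs from the end of the forward transposase anchor to the
    start of the universal reverse primer; a missing anchor's boundary is
    reconstructed from the predicted barcode coordinates.  Downstream
    identity thresholds assume this trim — barcode/anchor overhead would
    otherwise cap identity against any clean reference near 95%.
    """
    fwd = anchor_hits.get("fwd_transposase")
    univ = anchor_hits.get("univ_reverse_primer")
    start = fwd.end if fwd is not None else None
    end = univ.start if univ is not None else None
    if start is None and predicted.get("row") is not None:
        start = predicted["row"] + ROW_BARCODE_LEN + ANCHOR_LENGTHS["fwd_transposase"]
    if end is None and predicted.get("plate") is not None:
        end = predicted["plate"] - ANCHOR_LENGTHS["univ_reverse_primer"]
    if start is None or end is None or end <= max(0, start):
        return None
    return max(0, start), min(read_len, end)


def demultiplex_run(
    records: list[CCSRecord],
    manifest: BarcodeManifest,
    tolerance: int = POSITION_TOLERANCE,
) -> tuple[dict[WellAddress, list[CCSRecord]], list[DemuxResult], FilterLedger]:
    """Assign every read to exactly one well bin or the unassigned pool.

    Reads are re-oriented to construct plus strand and trimmed to their
    insert inside the bins, so downstream alignment thresholds see
    consistent, adapter-free sequence.
    """
    seen: set[str] = set()
    for r in records:
        if r.ccs_id in seen:
            raise ValueError(f"duplicate ccs_id {r.ccs_id!r}")
        seen.add(r.ccs_id)
    bins: dict[WellAddress, list[CCSRecord]] = {}
    results: list[DemuxResult] = []
    ledger = FilterLedger(assembled=len(records))
    for ccs in records:
        res = demultiplex_read(ccs, manifest, tolerance)
        results.append(res)
        if res.well is None:
            ledger.non_demultiplexed += 1
            continue
        oriented = (
            ccs.sequence
            if res.strand == "plus"
            else reverse_complement(ccs.sequence)
        )
        if res.insert_span is not None:
            lo, hi = res.insert_span
            oriented = oriented[lo:hi]
        assigned = ccs.advance("demultiplexed", well=res.well, sequence=oriented)
        bins.setdefault(res.well, []).append(assigned)
        ledger.demultiplexed += 1
    return bins, results, ledger


def demux_table(results: list[DemuxResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            dict(
                ccs_id=r.ccs_id,
                plate=r.well.plate_id if r.well else "",
                row=r.well.row if r.well else "",
                column=r.well.column if r.well else "",
                strand=r.strand,
                assigned=r.assigned,
                plate_call=r.barcode_calls["plate"].called_id or "",
                row_call=r.barcode_calls["row"].called_id or "",
                column_call=r.barcode_calls["column"].called_id or "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ccs_id", "plate", "row", "column", "strand", "assigned",
            "plate_call", "row_call", "column_call",
        ],
    )


def write_well_bins(
    bins: dict[WellAddress, list[CCSRecord]], outdir: str | Path
) -> None:
    """Per-well FASTA bins under a plate/well directory tree.

    Coverage rides along in the record description (``cov=N``) so a bin
    can be re-consumed by a downstream subcommand standalone.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    for well, reads in bins.items():
        d = outdir / well.plate_id
        d.mkdir(parents=True, exist_ok=True)
        recs = [
            SeqRecord(Seq(r.sequence), id=r.ccs_id, description=f"cov={r.coverage}")
            for r in reads
        ]
        SeqIO.write(recs, str(d / f"{well.label}.fasta"), "fasta")


def load_well_bins(indir: str | Path) -> dict[WellAddress, list[CCSRecord]]:
    """Read back a plate/well FASTA tree written by :func:`write_well_bins`."""
    from Bio import SeqIO

    indir = Path(indir)
    bins: dict[WellAddress, list[CCSRecord]] = {}
    for well_file in sorted(indir.glob("*/*.fasta")):
        label = well_file.stem
        well = WellAddress(well_file.parent.name, label[0], int(label[1:]))
        reads = []
        for rec in SeqIO.parse(str(well_file), "fasta"):
            cov = 0
            for field in rec.description.split():
                if field.startswith("cov="):
                    cov = int(field[4:])
            reads.append(
                CCSRecord(
                    rec.id, str(rec.seq).upper(), 0, coverage=cov,
                    well=well, status="demultiplexed",
                )
            )
        bins[well] = reads
    return bins
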