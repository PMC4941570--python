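"""Greedy centroid OTU clustering at 97% identity.

Reads are clustered *within each well* first (a well is one picked
colony community, so its diversity is tiny), then well centroids are
re-clustered across the whole collection to measure redundancy — how
many wells carry the same organism.

The greedy pass processes reads in a fixed total order (coverage
descending, then length descending, then id) so clustering is
deterministic regardless of input file order; each read joins the first
centroid at >= 97% identity or founds a new OTU, which guarantees every
new centroid is < 97% to all earlier centroids at founding time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import CCSRecord, WellAddress, coverage_class
from .seqkernel import identity_if_at_least

OTU_IDENTITY_THRESHOLD = 97.0


@dataclass
class OTU:
    otu_id: str
    well: WellAddress | None  # None at collection level
    centroid_id: str
    centroid_seq: str
    members: list[str] = field(default_factory=list)
    coverage_composition: dict[str, int] = field(
        default_factory=lambda: {"low": 0, "high": 0}
    )

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def singleton(self) -> bool:
        return self.size == 1


def _sort_key(r: CCSRecord) -> tuple:
    return (-r.coverage, -len(r.sequence), r.ccs_id)


def cluster_well(
    reads: list[CCSRecord],
    threshold: float = OTU_IDENTITY_THRESHOLD,
    well: WellAddress | None = None,
) -> list[OTU]:
    """Greedy centroid clustering of one well's usable reads."""
    if not reads:
        return []
    if well is None:
        well = reads[0].well
    otus: list[OTU] = []
    for r in sorted(reads, key=_sort_key):
        placed = False
        for otu in otus:
            ident = identity_if_at_least(r.sequence, otu.centroid_seq, threshold)
            if ident is not None and ident >= threshold:
                otu.members.append(r.ccs_id)
                otu.coverage_composition[coverage_class(r.coverage)] += 1
                placed = True
                break
        if not placed:
            label = well.label if well else "x"
            otu = OTU(
                otu_id=f"{well.plate_id if well else 'C'}.{label}.otu{len(otus) + 1}",
                well=well,
                centroid_id=r.ccs_id,
                centroid_seq=r.sequence,
            )
            otu.members.append(r.ccs_id)
            otu.coverage_composition[coverage_class(r.coverage)] += 1
            otus.append(otu)
    return otus


def cluster_all_wells(
    bins: dict[WellAddress, list[CCSRecord]],
    threshold: float = OTU_IDENTITY_THRESHOLD,
) -> list[OTU]:
    otus: list[OTU] = []
    for well in sorted(bins):
        otus.extend(cluster_well(bins[well], threshold, well))
    return otus


def recluster_collection(
    well_otus: list[OTU], threshold: float = OTU_IDENTITY_THRESHOLD
) -> tuple[list[OTU], dict[str, list[str]]]:
    """Re-cluster well-OTU centroids across the collection.

    Returns collection OTUs (members are well-OTU ids) and a redundancy
    map: collection OTU id -> wells sharing it.
    """
    collection: list[OTU] = []
    membership: dict[str, list[str]] = {}
    ordered = sorted(
        well_otus, key=lambda o: (-o.size, -len(o.centroid_seq), o.otu_id)
    )
    for wotu in ordered:
        placed = None
        for cotu in collection:
            ident = identity_if_at_least(
                wotu.centroid_seq, cotu.centroid_seq, threshold
            )
            if ident is not None and ident >= threshold:
                placed = cotu
                break
        if placed is None:
            placed = OTU(
                otu_id=f"collection.otu{len(collection) + 1}",
                well=None,
                centroid_id=wotu.centroid_id,
                centroid_seq=wotu.centroid_seq,
            )
            collection.append(placed)
            membership[placed.otu_id] = []
        placed.members.append(wotu.otu_id)
        for k, v in wotu.coverage_composition.items():
            placed.coverage_composition[k] += v
        membership[placed.otu_id].append(
            f"{wotu.well.plate_id}:{wotu.well.label}" if wotu.well else "?"
        )
    redundancy = {k: sorted(set(v)) for k, v in membership.items()}
    return collection, redundancy


def otu_well_summary(well_otus: list[OTU]) -> pd.DataFrame:
    """Per-well OTU counts plus singleton / coverage-composition stats."""
    rows = []
    for otu in well_otus:
        rows.append(
            dict(
                plate=otu.well.plate_id if otu.well else "",
                well=otu.well.label if otu.well else "",
                otu_id=otu.otu_id,
                size=otu.size,
                singleton=otu.singleton,
                n_low_coverage=otu.coverage_composition["low"],
                n_high_coverage=otu.coverage_composition["high"],
                mixed_coverage=(
                    otu.coverage_composition["low"] > 0
                    and otu.coverage_composition["high"] > 0
                ),
                centroid_id=otu.centroid_id,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "plate", "well", "otu_id", "size", "singleton",
            "n_low_coverage", "n_high_coverage", "mixed_coverage", "centroid_id",
        ],
    )


def singleton_counts(well_otus: list[OTU]) -> dict[str, int]:
    """Singleton OTUs split by the coverage class of their only read."""
    out = {"low": 0, "high": 0}
    for otu in well_otus:
        if otu.singleton:
            klass = "low" if otu.coverage_composition["low"] else "high"
            out[klass] += 1
    return out


def otu_table(otus: list[OTU]) -> pd.DataFrame:
    rows = [
        dict(
            otu_id=o.otu_id,
            plate=o.well.plate_id if o.well else "",
            well=o.well.label if o.well else "",
            size=o.size,
            singleton=o.singleton,
            centroid_id=o.centroid_id,
        )
        for o in otus
    ]
    return pd.DataFrame(
        rows, columns=["otu_id", "plate", "well", "size", "singleton", "centroid_id"]
    )
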