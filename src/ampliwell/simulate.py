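"""Synthetic multiplexed-run generator with per-read ground truth.

Emits exactly what the pipeline consumes — a consensus-read FASTA, a
subread-total TSV sidecar, the barcode manifest, a 16S-like reference
pool with lineages — plus a truth table recording, for every read, its
well of origin, template taxa, coverage, and whether it was injected as a
chimera, an off-target product or a barcode-corrupted read.

The generator reproduces the statistical structure of a real multiplexed
culture-collection run:

* construct layout ``[row bc][fwd anchor][insert][univ primer][plate bc]``
  ``[rev anchor][column bc]``, ~50% of reads emitted reverse-complemented;
* coverage-dependent per-base error classes — 2.3% below 5x, 0.7% for
  5-9x, 0.3% above 9x — applied i.i.d. with an 80/20 substitution/indel
  mix, and ~74.7% of reads drawn from the high-accuracy (>9x) class;
* chimeric (bimeric) inserts at 12.3% of reads and off-target inserts at
  0.14%, the rates observed in the motivating dataset;
* 93 sample wells per plate with 1..4 community members each, an
  H10 positive-control well seeded with a designated control taxon, and
  empty H11/H12 negative controls.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    BarcodeManifest,
    ROWS,
    WellAddress,
    default_manifest,
)
from .seqkernel import reverse_complement

BASES = np.array(list("ACGT"))

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the synthetic run; defaults are the study conditions."""

    seed: int = 1
    n_plates: int = 5
    taxa_pool_size: int = 24
    genus_size: int = 3
    amplicon_length_range: tuple[int, int] = (1250, 1450)
    # P(community size = k) for k = 1..len; over half of wells hold >= 2 members.
    community_size_distribution: tuple[float, ...] = (0.45, 0.30, 0.15, 0.10)
    # P(coverage class): mass over 2..40 with ~74.7% above 9x.
    coverage_values: tuple[int, ...] = tuple(range(2, 41))
    high_coverage_mass: float = 0.747
    error_rate_by_class: dict[str, float] = field(
        default_factory=lambda: {"cov<5": 0.023, "5<=cov<=9": 0.007, "cov>9": 0.003}
    )
    substitution_fraction: float = 0.8  # of errors; remainder split ins/del
    chimera_fraction: float = 0.123
    offtarget_fraction: float = 0.0014
    barcode_corruption_fraction: float = 0.02
    reads_per_well_range: tuple[int, int] = (3, 6)
    subread_jitter_fraction: float = 0.4  # |jitter| < 0.5 keeps coverage exact
    revcomp_fraction: float = 0.5

    def validate(self) -> None:
        for name in ("chimera_fraction", "offtarget_fraction",
                     "barcode_corruption_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0,1], got {v}")
        if self.chimera_fraction + self.offtarget_fraction > 0.5:
            raise SimulationError("chimera + offtarget fractions exceed 0.5")
        for k, v in self.error_rate_by_class.items():
            if not 0.0 <= v <= 0.1:
                raise SimulationError(f"error rate {k}={v} outside [0, 0.1]")
        if self.taxa_pool_size < 2:
            raise SimulationError("taxa_pool_size must be >= 2")
        lo, hi = self.reads_per_well_range
        if lo < 0 or hi < lo:
            raise SimulationError("invalid reads_per_well_range")
        if abs(sum(self.community_size_distribution) - 1.0) > 1e-9:
            raise SimulationError("community_size_distribution must sum to 1")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["amplicon_length_range"] = list(self.amplicon_length_range)
        d["community_size_distribution"] = list(self.community_size_distribution)
        d["coverage_values"] = list(self.coverage_values)
        d["reads_per_well_range"] = list(self.reads_per_well_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("amplicon_length_range", "community_size_distribution",
                  "coverage_values", "reads_per_well_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def error_rate_for_coverage(self, coverage: int) -> float:
        if coverage < 5:
            return self.error_rate_by_class["cov<5"]
        if coverage <= 9:
            return self.error_rate_by_class["5<=cov<=9"]
        return self.error_rate_by_class["cov>9"]


@dataclass
class ReferencePool:
    """Simulated 16S-like taxa organised into genera, with lineages."""

    sequences: dict[str, str]  # taxon_id -> sequence
    lineages: dict[str, str]  # taxon_id -> "domain;...;genus"
    control_taxon: str  # seeded into H10 positive-control wells

    def genus_of(self, taxon_id: str) -> str:
        return self.lineages[taxon_id].split(";")[-1]

    def to_files(self, fasta_path: str | Path, lineage_path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=tid, description="")
            for tid, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        pd.DataFrame(
            [(tid, lin) for tid, lin in self.lineages.items()],
            columns=["taxon_id", "lineage"],
        ).to_csv(lineage_path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each position independently with probability ``rate``."""
    arr = np.array(list(seq))
    mask = rng.random(arr.size) < rate
    idx = np.nonzero(mask)[0]
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def build_reference_pool(config: SimulationConfig) -> ReferencePool:
    """Generate genera of >=3 taxa each: within-genus identity >=97%,
    between-genus identity <=90% (independent random ancestors sit far
    below that), deterministic under the config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genera, rem = divmod(config.taxa_pool_size, config.genus_size)
    if n_genera < 1:
        raise SimulationError(
            "taxa_pool_size smaller than genus_size — divergence constraints infeasible"
        )
    sizes = [config.genus_size] * n_genera
    if rem:
        sizes[-1] += rem
    lo, hi = config.amplicon_length_range
    phyla = ["Acidofirmes", "Rubroflexi"]
    sequences: dict[str, str] = {}
    lineages: dict[str, str] = {}
    for g, size in enumerate(sizes):
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_seq(rng, length)
        lineage = (
            f"Bacteria;{phyla[g % 2]};Class{g % 4};Order{g % 4};"
            f"Family{g};Genus{g}"
        )
        for m in range(size):
            tid = f"T{g:02d}.{m}"
            # 1% substitutions per member keeps every within-genus pair
            # at >=97% expected identity (~98%).
            sequences[tid] = _mutate(rng, ancestor, 0.01)
            lineages[tid] = lineage
    control = next(iter(sequences))
    return ReferencePool(sequences, lineages, control)


def assign_well_communities(
    config: SimulationConfig, pool: ReferencePool
) -> dict[WellAddress, list[str]]:
    """Seed each sample well with 1..k taxa; H10 gets the control taxon,
    H11/H12 stay empty."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    taxa = [t for t in pool.sequences if t != pool.control_taxon]
    if not taxa:
        taxa = list(pool.sequences)
    sizes = np.arange(1, len(config.community_size_distribution) + 1)
    communities: dict[WellAddress, list[str]] = {}
    for p in range(1, config.n_plates + 1):
        plate_id = f"P{p}"
        for row in ROWS:
            for col in range(1, 13):
                well = WellAddress(plate_id, row, col)
                if well.is_negative_control:
                    continue
                if well.is_positive_control:
                    communities[well] = [pool.control_taxon]
                    continue
                k = int(rng.choice(sizes, p=config.community_size_distribution))
                k = min(k, len(taxa))
                members = rng.choice(len(taxa), size=k, replace=False)
                communities[well] = [taxa[i] for i in members]
    return communities


def _draw_coverage(config: SimulationConfig, rng: np.random.Generator) -> int:
    values = np.array(config.coverage_values)
    low = values[values <= 9]
    high = values[values > 9]
    if rng.random() < config.high_coverage_mass and high.size:
        return int(rng.choice(high))
    return int(rng.choice(low if low.size else values))


def _apply_errors(
    rng: np.random.Generator, seq: str, rate: float, sub_frac: float
) -> str:
    """i.i.d. per-base errors: ``sub_frac`` substitutions, the remainder
    split evenly between single-base insertions and deletions."""
    if rate <= 0:
        return seq
    out: list[str] = []
    p_sub = rate * sub_frac
    p_ins = rate * (1 - sub_frac) / 2
    p_del = rate * (1 - sub_frac) / 2
    draws = rng.random(len(seq))
    for i, base in enumerate(seq):
        r = draws[i]
        if r < p_sub:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(0, 3)])
        elif r < p_sub + p_del:
            continue
        elif r < p_sub + p_del + p_ins:
            out.append(base)
            out.append(BASES[rng.integers(0, 4)])
        else:
            out.append(base)
    return "".join(out) if out else seq


def _make_bimera(
    rng: np.random.Generator,
    pool: ReferencePool,
    plate_taxa: list[str],
) -> tuple[str, str, str, int] | None:
    """Two-parent chimera from different genera on the same plate;
    crossover uniform in the middle 60% of the insert."""
    genera: dict[str, list[str]] = {}
    for t in plate_taxa:
        genera.setdefault(pool.genus_of(t), []).append(t)
    if len(genera) < 2:
        return None
    ga, gb = rng.choice(len(genera), size=2, replace=False)
    keys = list(genera)
    pa = genera[keys[ga]][rng.integers(0, len(genera[keys[ga]]))]
    pb = genera[keys[gb]][rng.integers(0, len(genera[keys[gb]]))]
    sa, sb = pool.sequences[pa], pool.sequences[pb]
    n = min(len(sa), len(sb))
    lo, hi = int(0.2 * n), int(0.8 * n)
    cross = int(rng.integers(lo, hi))
    return sa[:cross] + sb[cross:], pa, pb, cross


def _build_construct(
    manifest: BarcodeManifest, well: WellAddress, insert: str
) -> str:
    return (
        manifest.row_barcodes[well.row]
        + manifest.anchors["fwd_transposase"]
        + insert
        + manifest.anchors["univ_reverse_primer"]
        + manifest.plate_barcodes[well.plate_id]
        + manifest.anchors["rev_transposase"]
        + manifest.column_barcodes[well.column]
    )


def _corrupt_one_barcode(
    rng: np.random.Generator, construct: str, insert_len: int
) -> str:
    # Pick one barcode region and mutate 1-2 of its positions.
    regions = {
        "row": (0, 8),
        "plate": (8 + 14 + insert_len + 16, 8 + 14 + insert_len + 16 + 9),
        "column": (len(construct) - 8, len(construct)),
    }
    klass = ["row", "plate", "column"][rng.integers(0, 3)]
    lo, hi = regions[klass]
    arr = list(construct)
    n_mut = int(rng.integers(1, 3))
    pos = rng.choice(np.arange(lo, hi), size=n_mut, replace=False)
    for i in pos:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def synthesize_run(
    config: SimulationConfig,
    manifest: BarcodeManifest,
    communities: dict[WellAddress, list[str]],
    pool: ReferencePool,
) -> tuple[list[SeqRecord], pd.DataFrame, pd.DataFrame]:
    """Emit reads for every seeded well.

    Returns (FASTA records, subread sidecar frame, truth table frame).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    records: list[SeqRecord] = []
    sidecar_rows: list[tuple[str, int]] = []
    truth_rows: list[dict] = []
    plate_taxa: dict[str, list[str]] = {}
    for well, members in communities.items():
        plate_taxa.setdefault(well.plate_id, [])
        for m in members:
            if m not in plate_taxa[well.plate_id]:
                plate_taxa[well.plate_id].append(m)
    read_no = 0
    lo_rpw, hi_rpw = config.reads_per_well_range
    lo_len, hi_len = config.amplicon_length_range
    for well in sorted(communities):
        members = communities[well]
        n_reads = int(rng.integers(lo_rpw, hi_rpw + 1))
        for _ in range(n_reads):
            read_no += 1
            ccs_id = f"ccs{read_no:06d}"
            taxon = members[rng.integers(0, len(members))]
            is_chimera = False
            is_offtarget = False
            parent_a = parent_b = ""
            crossover = -1
            u = rng.random()
            if u < config.chimera_fraction:
                bim = _make_bimera(rng, pool, plate_taxa[well.plate_id])
                if bim is not None:
                    insert, parent_a, parent_b, crossover = bim
                    is_chimera = True
                    taxon = ""
                else:
                    insert = pool.sequences[taxon]
            elif u < config.chimera_fraction + config.offtarget_fraction:
                insert = _random_seq(rng, int(rng.integers(lo_len, hi_len + 1)))
                is_offtarget = True
                taxon = ""
            else:
                insert = pool.sequences[taxon]

            construct = _build_construct(manifest, well, insert)
            is_corrupted = rng.random() < config.barcode_corruption_fraction
            if is_corrupted:
                construct = _corrupt_one_barcode(rng, construct, len(insert))
            coverage = _draw_coverage(config, rng)
            rate = config.error_rate_for_coverage(coverage)
            read = _apply_errors(rng, construct, rate, config.substitution_fraction)
            if rng.random() < config.revcomp_fraction:
                read = reverse_complement(read)
            jitter_max = config.subread_jitter_fraction * len(read)
            jitter = int(rng.uniform(-jitter_max, jitter_max))
            subread_total = coverage * len(read) + jitter
            records.append(SeqRecord(Seq(read), id=ccs_id, description=""))
            sidecar_rows.append((ccs_id, subread_total))
            truth_rows.append(
                dict(
                    ccs_id=ccs_id,
                    true_plate=well.plate_id,
                    true_row=well.row,
                    true_column=well.column,
                    true_taxon=taxon,
                    is_chimera=is_chimera,
                    parent_a=parent_a,
                    parent_b=parent_b,
                    crossover_position=crossover,
                    is_offtarget=is_offtarget,
                    is_barcode_corrupted=is_corrupted,
                    true_coverage=coverage,
                )
            )
    sidecar = pd.DataFrame(sidecar_rows, columns=["ccs_id", "subread_total_nt"])
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "ccs_id", "true_plate", "true_row", "true_column", "true_taxon",
            "is_chimera", "parent_a", "parent_b", "crossover_position",
            "is_offtarget", "is_barcode_corrupted", "true_coverage",
        ],
    )
    return records, sidecar, truth


def build_community_profile(
    pool: ReferencePool,
    config: SimulationConfig,
    fragment: tuple[int, int] = (400, 650),
    compartments: tuple[str, ...] = (
        "rhizosphere", "endophytic_root", "endophytic_stalk",
    ),
) -> pd.DataFrame:
    """Culture-independent community profile built from the reference pool.

    Each taxon contributes one short (~250 nt, V4-like) representative
    fragment per compartment with a random relative abundance; abundances
    sum to 1 within a compartment.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    rows = []
    taxa = list(pool.sequences)
    for comp in compartments:
        weights = rng.dirichlet(np.ones(len(taxa)))
        for tid, w in zip(taxa, weights):
            seq = pool.sequences[tid]
            lo, hi = fragment
            hi = min(hi, len(seq))
            rows.append(
                dict(
                    profile_otu_id=f"{comp}|{tid}",
                    representative=seq[lo:hi],
                    compartment=comp,
                    relative_abundance=float(w),
                    source_taxon=tid,
                )
            )
    return pd.DataFrame(rows)


@dataclass
class SimulatedRun:
    config: SimulationConfig
    manifest: BarcodeManifest
    pool: ReferencePool
    communities: dict[WellAddress, list[str]]
    records: list[SeqRecord]
    sidecar: pd.DataFrame
    truth: pd.DataFrame


def simulate_run(config: SimulationConfig | None = None) -> SimulatedRun:
    """One-call generator: manifest + pool + communities + reads + truth."""
    config = config or SimulationConfig()
    config.validate()
    manifest = default_manifest(config.n_plates)
    pool = build_reference_pool(config)
    communities = assign_well_communities(config, pool)
    records, sidecar, truth = synthesize_run(config, manifest, communities, pool)
    return SimulatedRun(config, manifest, pool, communities, records, sidecar, truth)


def write_run(run: SimulatedRun, outdir: str | Path) -> dict[str, Path]:
    """Write every simulator output under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ccs": outdir / "ccs.fasta",
        "subreads": outdir / "subreads.tsv",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "manifest.tsv",
        "references": outdir / "references.fasta",
        "lineages": outdir / "lineages.tsv",
        "config": outdir / "simulation.yaml",
    }
    SeqIO.write(run.records, str(paths["ccs"]), "fasta")
    run.sidecar.to_csv(paths["subreads"], sep="\t", index=False)
    run.truth.to_csv(paths["truth"], sep="\t", index=False)
    run.manifest.to_tsv(paths["manifest"])
    run.pool.to_files(paths["references"], paths["lineages"])
    run.config.to_yaml(paths["config"])
    return paths
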