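"""Greedy centroid clustering and its brute-force optimal-partition oracle."""

import numpy as np
import pytest

from ampliwell.cluster import (
    cluster_well,
    otu_well_summary,
    recluster_collection,
    singleton_counts,
)
from ampliwell.model import CCSRecord, WellAddress
from ampliwell.seqkernel import global_identity
from conftest import mutate, random_seq

WELL = WellAddress("P1", "B", 4)


def read(i, seq, cov=12):
    return CCSRecord(f"r{i}", seq, cov * len(seq), well=WELL)


class TestClusterWell:
    def test_two_templates_two_otus(self, rng):
        a = random_seq(rng, 600)
        b = mutate(rng, a, 0.10)  # ~90% identity
        reads = [read(1, a), read(2, a), read(3, a), read(4, b)]
        otus = cluster_well(reads)
        assert sorted(o.size for o in otus) == [1, 3]
        assert sum(o.singleton for o in otus) == 1

    def test_all_similar_reads_form_one_otu(self, rng):
        a = random_seq(rng, 600)
        reads = [read(i, mutate(rng, a, 0.005)) for i in range(6)]
        otus = cluster_well(reads)
        assert len(otus) == 1 and otus[0].size == 6

    def test_empty_well_yields_no_otus(self):
        assert cluster_well([]) == []

    def test_centroid_is_highest_coverage_read(self, rng):
        a = random_seq(rng, 600)
        reads = [read(1, a, cov=5), read(2, mutate(rng, a, 0.005), cov=30)]
        otus = cluster_well(reads)
        assert otus[0].centroid_id == "r2"

    def test_determinism_under_input_order(self, rng):
        a, b = random_seq(rng, 600), random_seq(rng, 600)
        reads = [read(i, mutate(rng, a if i % 2 else b, 0.01), cov=int(c))
                 for i, c in enumerate(rng.integers(2, 40, size=8))]
        ref = cluster_well(list(reads))
        for _ in range(3):
            rng.shuffle(reads)
            got = cluster_well(list(reads))
            assert [(o.centroid_id, sorted(o.members)) for o in got] == [
                (o.centroid_id, sorted(o.members)) for o in ref
            ]


def optimal_star_partition_size(reads, threshold=97.0):
    """Minimum number of clusters such that each has a member (centroid)
    within ``threshold`` identity of every other member — exact set-cover
    DP over star neighbourhoods."""
    n = len(reads)
    ident = np.zeros((n, n), dtype=bool)
    for i in range(n):
        ident[i, i] = True
        for j in range(i + 1, n):
            ok = (
                global_identity(reads[i].sequence, reads[j].sequence).identity
                >= threshold
            )
            ident[i, j] = ident[j, i] = ok
    stars = [sum(1 << j for j in range(n) if ident[c, j]) for c in range(n)]
    full = (1 << n) - 1
    dp = {0: 0}

    def solve(mask):
        if mask in dp:
            return dp[mask]
        v = (mask & -mask).bit_length() - 1  # lowest uncovered read
        best = min(
            solve(mask & ~stars[c]) for c in range(n) if stars[c] >> v & 1
        )
        dp[mask] = best + 1
        return dp[mask]

    return solve(full)


class TestOracleEquivalence:
    def test_greedy_matches_optimal_partition_on_100_random_wells(self):
        """Greedy centroid clustering finds the optimal 97% partition on
        wells of <= 10 reads drawn from well-separated templates."""
        rng = np.random.default_rng(1003)
        templates = [random_seq(rng, 500) for _ in range(8)]
        for _ in range(100):
            k = int(rng.integers(1, 4))
            chosen = rng.choice(8, size=k, replace=False)
            n_reads = int(rng.integers(k, 11))
            reads = []
            used = set()
            for i in range(n_reads):
                t = int(chosen[i % k])
                used.add(t)
                reads.append(
                    read(i, mutate(rng, templates[t], 0.005),
                         cov=int(rng.integers(2, 40)))
                )
            otus = cluster_well(reads)
            assert len(otus) == optimal_star_partition_size(reads) == len(used)

    def test_membership_equals_template_truth(self, rng):
        a, b = random_seq(rng, 700), random_seq(rng, 700)
        truth = {}
        reads = []
        for i in range(10):
            t = "a" if i % 2 else "b"
            truth[f"r{i}"] = t
            reads.append(read(i, mutate(rng, a if t == "a" else b, 0.01)))
        otus = cluster_well(reads)
        assert len(otus) == 2
        for o in otus:
            assert len({truth[m] for m in o.members}) == 1


class TestInvariants:
    def test_every_usable_read_in_exactly_one_otu(self, qc_result, well_otus):
        usable_ids = sorted(
            r.ccs_id for reads in qc_result.usable.values() for r in reads
        )
        member_ids = sorted(m for o in well_otus for m in o.members)
        assert member_ids == usable_ids

    def test_members_within_97_of_centroid(self, qc_result, well_otus):
        reads = {
            r.ccs_id: r.sequence
            for rs in qc_result.usable.values()
            for r in rs
        }
        for o in well_otus:
            for m in o.members:
                assert (
                    global_identity(reads[m], o.centroid_seq).identity >= 97.0
                )

    def test_every_well_otu_in_exactly_one_collection_otu(self, well_otus):
        coll, redundancy = recluster_collection(well_otus)
        placed = sorted(m for o in coll for m in o.members)
        assert placed == sorted(o.otu_id for o in well_otus)
        assert set(redundancy) == {o.otu_id for o in coll}


class TestRecluster:
    def test_shared_taxon_across_wells_merges(self, rng):
        seq = random_seq(rng, 700)
        w1 = WellAddress("P1", "A", 1)
        w2 = WellAddress("P2", "C", 5)
        otus = (
            cluster_well([CCSRecord("x", mutate(rng, seq, 0.005), 7000, well=w1)], well=w1)
            + cluster_well([CCSRecord("y", mutate(rng, seq, 0.005), 7000, well=w2)], well=w2)
        )
        coll, redundancy = recluster_collection(otus)
        assert len(coll) == 1
        assert redundancy[coll[0].otu_id] == ["P1:A1", "P2:C5"]

    def test_distinct_taxa_stay_separate(self, rng):
        otus = []
        for i, w in enumerate(
            [WellAddress("P1", "A", 1), WellAddress("P1", "A", 2)]
        ):
            otus += cluster_well(
                [CCSRecord(f"z{i}", random_seq(rng, 700), 7000, well=w)], well=w
            )
        coll, _ = recluster_collection(otus)
        assert len(coll) == 2

    def test_empty_input(self):
        coll, redundancy = recluster_collection([])
        assert coll == [] and redundancy == {}


class TestSummaries:
    def test_counts_and_singletons(self, rng):
        a = random_seq(rng, 600)
        b = mutate(rng, a, 0.1)
        otus = cluster_well([read(1, a), read(2, a), read(3, a), read(4, b)])
        df = otu_well_summary(otus)
        assert len(df) == 2
        assert df["singleton"].sum() == 1

    def test_empty_summary(self):
        assert otu_well_summary([]).empty

    def test_low_coverage_reads_mostly_cluster_with_high(
        self, qc_result, well_otus, truth_by_id
    ):
        """Where a well also holds high-coverage reads of the same taxon,
        low-coverage reads overwhelmingly join mixed-coverage OTUs."""
        cov = {}
        high_taxa_by_well = {}  # well -> taxa with a high-coverage read
        for well, reads in qc_result.usable.items():
            taxa = set()
            for r in reads:
                cov[r.ccs_id] = r.coverage
                if r.coverage >= 10:
                    taxa.add(truth_by_id.loc[r.ccs_id, "true_taxon"])
            high_taxa_by_well[well] = taxa
        eligible = with_high = 0
        for o in well_otus:
            has_high = any(cov[m] >= 10 for m in o.members)
            for m in o.members:
                if cov[m] >= 10:
                    continue
                taxon = truth_by_id.loc[m, "true_taxon"]
                if taxon not in high_taxa_by_well[o.well]:
                    continue
                eligible += 1
                with_high += has_high
        assert eligible > 20
        assert with_high / eligible >= 0.9

    def test_singleton_counts_by_coverage_class(self, well_otus):
        counts = singleton_counts(well_otus)
        n_singletons = sum(1 for o in well_otus if o.singleton)
        assert counts["low"] + counts["high"] == n_singletons
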