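"""QC cascade: length, chimera, nonspecific and reliability filters."""

import numpy as np
import pytest

from ampliwell.model import CCSRecord, WellAddress
from ampliwell.qc import (
    chimera_filter,
    classify_chimera,
    coverage_filter,
    length_filter,
    nonspecific_filter,
    reliability_filter,
    run_qc,
    two_segment_identity,
)
from ampliwell.seqkernel import EmptyDatabaseError, global_identity
from conftest import mutate, random_seq


def one_bin(*reads):
    return {WellAddress("P1", "A", 1): list(reads)}


def flat(bins):
    return sorted(r.ccs_id for reads in bins.values() for r in reads)


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,kept", [(1600, True), (1601, False), (1400, True)]
    )
    def test_strict_boundary_at_1600(self, length, kept, rng):
        r = CCSRecord("r1", random_seq(rng, length), 10 * length)
        bins, dropped = length_filter(one_bin(r))
        assert (flat(bins) == ["r1"]) == kept
        if not kept:
            assert dropped[0].status == "discarded_length"


@pytest.fixture(scope="module")
def parents():
    rng = np.random.default_rng(42)
    return [(f"p{i}", random_seq(rng, 1300)) for i in range(6)]


class TestChimeraFilter:

    def test_read_identical_to_reference_is_not_chimera(self, parents):
        r = CCSRecord("r1", parents[2][1], 13000)
        verdict = classify_chimera(r, parents)
        assert not verdict.is_chimera

    def test_constructed_bimera_is_flagged_with_parents(self, parents):
        pa, pb = parents[0][1], parents[1][1]
        cross = 640
        r = CCSRecord("bim", pa[:cross] + pb[cross:], 13000)
        verdict = classify_chimera(r, parents)
        assert verdict.is_chimera
        assert {verdict.parent_a, verdict.parent_b} == {"p0", "p1"}

    def test_crossover_recovered_within_20_nt_of_oracle(self, parents):
        """Brute force oracle: the best single crossover is found by
        scoring the read against every explicit A[:c]+B[c:] hybrid."""
        pa, pb = parents[0][1], parents[1][1]
        cross = 700
        read = pa[:cross] + pb[cross:]
        _, got = two_segment_identity(read, pa, pb)
        best_c, best_ident = None, -1.0
        for c in range(100, len(read) - 100, 10):
            ident = global_identity(read, pa[:c] + pb[c:]).identity
            if ident > best_ident:
                best_ident, best_c = ident, c
        assert abs(got - best_c) <= 20
        assert abs(got - cross) <= 20

    def test_false_positive_rate_below_1pct(self, qc_result, truth_by_id):
        verdicts = qc_result.chimera_verdicts
        non_chim = [
            v for v in verdicts if not truth_by_id.loc[v.ccs_id, "is_chimera"]
        ]
        fp = sum(1 for v in non_chim if v.is_chimera)
        assert len(non_chim) >= 1500
        assert fp / len(non_chim) <= 0.01

    def test_detects_injected_bimeras(self, qc_result, truth_by_id):
        verdicts = {v.ccs_id: v for v in qc_result.chimera_verdicts}
        true_chim = [i for i in verdicts if truth_by_id.loc[i, "is_chimera"]]
        assert len(true_chim) >= 100
        found = sum(1 for i in true_chim if verdicts[i].is_chimera)
        assert found / len(true_chim) >= 0.9

    def test_heuristic_agrees_with_exhaustive_parent_search(
        self, qc_result, truth_by_id, reference_db, rng
    ):
        reads = [r for reads in qc_result.usable.values() for r in reads]
        chim = [
            r
            for reads in [qc_result.discarded["chimeric"]]
            for r in reads
        ]
        sample = list(rng.choice(len(reads), size=40, replace=False))
        subset = [reads[int(i)] for i in sample] + chim[:20]
        agree = 0
        for r in subset:
            fast = classify_chimera(r, reference_db)
            slow = classify_chimera(r, reference_db, exhaustive=True)
            agree += fast.is_chimera == slow.is_chimera
        assert agree / len(subset) >= 0.99

    def test_empty_database_is_configuration_error(self, rng):
        r = CCSRecord("r1", random_seq(rng, 500), 5000)
        with pytest.raises(EmptyDatabaseError):
            classify_chimera(r, [])


class TestNonspecificFilter:
    def test_random_insert_discarded_true_read_kept(self, rng):
        db = [(f"ref{i}", random_seq(rng, 1300)) for i in range(10)]
        good = CCSRecord("good", mutate(rng, db[4][1], 0.02), 13000)
        offtarget = CCSRecord("off", random_seq(rng, 1300), 13000)
        bins, dropped = nonspecific_filter(one_bin(good, offtarget), db)
        assert flat(bins) == ["good"]
        assert dropped[0].ccs_id == "off"
        assert dropped[0].status == "discarded_nonspecific"

    def test_exactly_75_percent_identity_passes(self):
        """The rule discards strictly below 75%."""
        base = "ACGT" * 25  # 100 nt
        # 25 dispersed substitutions -> exactly 75 matching columns
        arr = list(base)
        for i in range(0, 100, 4):
            arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
        query = "".join(arr)
        assert global_identity(query, base).identity == pytest.approx(75.0)
        bins, dropped = nonspecific_filter(
            one_bin(CCSRecord("q", query, 1000)), [("ref", base)]
        )
        assert flat(bins) == ["q"]


class TestReliabilityFilter:
    def test_database_hit(self, rng):
        ref = random_seq(rng, 1300)
        read = CCSRecord("r1", mutate(rng, ref, 0.02), 13000)  # ~98%
        usable, dropped, verdicts = reliability_filter(
            one_bin(read), [("ref", ref)]
        )
        assert verdicts[0].source == "database_hit"
        assert flat(usable) == ["r1"]
        assert usable[WellAddress("P1", "A", 1)][0].reliability_source == "database_hit"

    def test_dataset_hit_when_database_misses(self, rng):
        """A read absent from the curated database is rescued by a 97.5%
        twin elsewhere in the run."""
        taxon = random_seq(rng, 1300)
        twin_a = CCSRecord("a", mutate(rng, taxon, 0.01), 13000)
        twin_b = CCSRecord("b", mutate(rng, taxon, 0.012), 13000)
        unrelated_db = [("far", random_seq(rng, 1300))]
        usable, dropped, verdicts = reliability_filter(
            one_bin(twin_a, twin_b), unrelated_db
        )
        assert {v.source for v in verdicts} == {"dataset_hit"}
        assert flat(usable) == ["a", "b"]

    def test_error_prone_when_both_stages_miss(self, rng):
        lonely = CCSRecord("x", random_seq(rng, 1300), 13000)
        other = CCSRecord("y", random_seq(rng, 1300), 13000)
        db = [("far", random_seq(rng, 1300))]
        usable, dropped, verdicts = reliability_filter(one_bin(lonely, other), db)
        assert usable == {}
        assert {r.status for r in dropped} == {"error_prone"}
        assert {v.source for v in verdicts} == {"none"}

    def test_superset_of_coverage_filter_for_db_hit_reads(
        self, qc_result, reference_db
    ):
        """Every read passing the coverage filter with a >= 97% database
        hit is also retained by the reliability filter — and so are
        db-hit reads the coverage filter would discard."""
        from ampliwell.seqkernel import db_search

        usable_ids = {r.ccs_id for reads in qc_result.usable.values() for r in reads}
        verdicts = {v.ccs_id: v for v in qc_result.reliability_verdicts}
        for v in verdicts.values():
            if v.source == "database_hit":
                assert v.ccs_id in usable_ids

    def test_retains_at_least_as_many_as_coverage_filter(self, qc_result):
        assert qc_result.ledger.usable_reliable >= qc_result.ledger.usable_cov_ge10


class TestCoverageFilter:
    def test_boundary_at_10x(self, rng):
        seq = random_seq(rng, 1000)
        r10 = CCSRecord("hi", seq, 10_000)
        r9 = CCSRecord("lo", seq, 9_000)
        bins, dropped = coverage_filter(one_bin(r10, r9))
        assert flat(bins) == ["hi"]
        assert dropped[0].ccs_id == "lo"


class TestRunQC:
    def test_clean_run_discards_nothing(self, rng):
        db = [(f"ref{i}", random_seq(rng, 1300)) for i in range(5)]
        reads = one_bin(
            *[CCSRecord(f"r{i}", db[i][1], 13000) for i in range(5)]
        )
        result = run_qc(reads, db, db)
        assert result.ledger.over_length == 0
        assert result.ledger.chimeric == 0
        assert result.ledger.nonspecific == 0
        assert result.ledger.error_prone == 0
        assert result.ledger.usable_reliable == 5

    def test_realized_chimera_discard_within_3_se(self, qc_result, default_sim):
        n = qc_result.ledger.demultiplexed
        p = default_sim.config.chimera_fraction
        se = np.sqrt(p * (1 - p) / n)
        assert abs(qc_result.ledger.chimeric / n - p) <= 3 * se

    def test_realized_offtarget_discard_within_3_se(self, qc_result, default_sim):
        n = qc_result.ledger.demultiplexed
        p = default_sim.config.offtarget_fraction
        se = np.sqrt(p * (1 - p) / n)
        assert abs(qc_result.ledger.nonspecific / n - p) <= 3 * se

    def test_ledger_conservation_identities(self, qc_result):
        assert qc_result.ledger.violations() == []

    def test_filter_idempotence(self, qc_result, reference_db):
        """Re-running any filter on its own survivors changes nothing."""
        usable = qc_result.usable
        again, dropped = length_filter(usable)
        assert dropped == [] and flat(again) == flat(usable)
        again, dropped = nonspecific_filter(usable, reference_db)
        assert dropped == [] and flat(again) == flat(usable)
        again, dropped, _ = chimera_filter(usable, reference_db)
        assert dropped == [] and flat(again) == flat(usable)

    def test_wells_recovered_counts(self, qc_result):
        assert qc_result.ledger.wells_recovered_reliable <= (
            qc_result.ledger.wells_recovered_pre
        )
        assert qc_result.ledger.wells_recovered_cov <= (
            qc_result.ledger.wells_recovered_pre
        )
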