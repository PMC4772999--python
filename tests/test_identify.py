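import random

import numpy as np
import pytest

from barcodekit.distances import distance_matrix
from barcodekit.identify import (
    all_species_barcodes,
    best_close_match,
    best_match,
    consensus_barcode,
    consensus_uniqueness,
    identification_report,
    tree_id_hebert,
    tree_id_meier,
)
from barcodekit.simulate import ScenarioConfig, make_scenario
from barcodekit.trees import nj_tree

from conftest import matrix_from_array, record


def _recs(*specs):
    """Records from (id, species) pairs; distances supplied separately."""
    return [record(i, "ACGT", species=s) for i, s in specs]


class TestBestMatch:
    def test_nearest_conspecific_wins(self):
        recs = _recs(("q", "A"), ("a", "A"), ("b", "B"))
        m = matrix_from_array(
            ["q", "a", "b"],
            [[0, 0.01, 0.05], [0.01, 0, 0.06], [0.05, 0.06, 0]],
        )
        assert best_match("q", m, recs).verdict == "success"

    def test_singleton_species_misidentified(self):
        recs = _recs(("q", "A"), ("b", "B"), ("c", "B"))
        m = matrix_from_array(
            ["q", "b", "c"],
            [[0, 0.04, 0.05], [0.04, 0, 0.01], [0.05, 0.01, 0]],
        )
        assert best_match("q", m, recs).verdict == "misidentified"

    def test_exact_tie_is_ambiguous(self):
        recs = _recs(("q", "A"), ("a", "A"), ("b", "B"))
        m = matrix_from_array(
            ["q", "a", "b"],
            [[0, 0.02, 0.02], [0.02, 0, 0.05], [0.02, 0.05, 0]],
        )
        out = best_match("q", m, recs)
        assert out.verdict == "ambiguous"
        assert set(out.evidence) == {"a", "b"}


class TestBestCloseMatch:
    def test_within_threshold_success(self):
        recs = _recs(("q", "A"), ("a", "A"))
        m = matrix_from_array(["q", "a"], [[0, 0.005], [0.005, 0]])
        assert best_close_match("q", m, recs, 0.01).verdict == "success"

    def test_nothing_within_threshold(self):
        recs = _recs(("q", "A"), ("a", "A"))
        m = matrix_from_array(["q", "a"], [[0, 0.04], [0.04, 0]])
        assert best_close_match("q", m, recs, 0.01).verdict == "no_match"

    def test_threshold_inclusive(self):
        recs = _recs(("q", "A"), ("a", "A"))
        m = matrix_from_array(["q", "a"], [[0, 0.01], [0.01, 0]])
        assert best_close_match("q", m, recs, 0.01).verdict == "success"


class TestAllSpeciesBarcodes:
    def setup_method(self):
        self.recs = _recs(("q", "A"), ("a1", "A"), ("a2", "A"), ("b", "B"))
        self.ids = ["q", "a1", "a2", "b"]

    def _m(self, d_qa2, d_qb=0.2):
        d = np.array(
            [
                [0, 0.005, d_qa2, d_qb],
                [0.005, 0, 0.006, 0.2],
                [d_qa2, 0.006, 0, 0.2],
                [d_qb, 0.2, 0.2, 0],
            ]
        )
        return matrix_from_array(self.ids, d)

    def test_full_conspecific_set_is_success(self):
        out = all_species_barcodes("q", self._m(0.008), self.recs, 0.01)
        assert out.verdict == "success"

    def test_incomplete_conspecific_set_is_ambiguous(self):
        out = all_species_barcodes("q", self._m(0.05), self.recs, 0.01)
        assert out.verdict == "ambiguous"

    def test_only_allospecific_within_is_misidentified(self):
        out = all_species_barcodes("q", self._m(0.05, d_qb=0.004), self.recs, 0.0045)
        assert out.verdict == "misidentified"

    def test_empty_set_is_no_match(self):
        out = all_species_barcodes("q", self._m(0.05), self.recs, 0.001)
        assert out.verdict == "no_match"


class TestIdentificationReport:
    def test_clean_gap_gives_full_success(self, two_genus_records):
        recs = [r for r in two_genus_records if r.species != "spD"]
        m = distance_matrix(recs, 1)
        report = identification_report(recs, m, [0.2])
        for crit in ("best_match", "best_close_match", "all_species_barcodes"):
            assert report.percent(crit, "success",
                                  None if crit == "best_match" else 0.2) == 100.0

    def test_singleton_query_verdicts(self, two_genus_records):
        m = distance_matrix(two_genus_records, 1)
        report = identification_report(two_genus_records, m, [0.01])
        for o in report.outcomes:
            if o.query_id != "d1":
                continue
            if o.criterion == "best_match":
                assert o.verdict == "misidentified"
            elif o.criterion == "best_close_match":
                assert o.verdict == "no_match"

    def test_percentages_partition_queries(self, two_genus_records):
        m = distance_matrix(two_genus_records, 1)
        report = identification_report(two_genus_records, m, [0.01, 0.1])
        sums = report.counts.groupby(["criterion", "threshold"], dropna=False)[
            "percent"
        ].sum()
        assert np.allclose(sums, 100.0)

    def test_success_implication_chain(self):
        # success under all_species_barcodes implies success under
        # best_close_match implies success under best_match
        rng = random.Random(23)
        for trial in range(10):
            n = rng.randint(4, 8)
            recs = [
                record(
                    f"s{i}",
                    "".join(rng.choice("ACGT") for _ in range(20)),
                    species=f"sp{i % 3}",
                )
                for i in range(n)
            ]
            m = distance_matrix(recs, 1)
            thr = rng.choice([0.05, 0.2, 0.5])
            for r in recs:
                asb = all_species_barcodes(r.id, m, recs, thr).verdict
                bcm = best_close_match(r.id, m, recs, thr).verdict
                bm = best_match(r.id, m, recs).verdict
                if asb == "success":
                    assert bcm == "success"
                if bcm == "success":
                    assert bm == "success"


class TestConsensus:
    def test_single_sequence_is_identity(self):
        assert consensus_barcode([record("a", "ACGT")]) == "ACGT"

    def test_majority_per_site(self):
        recs = [record("a", "AAAT"), record("b", "AAAC"), record("c", "AAAT")]
        assert consensus_barcode(recs) == "AAAT"

    def test_tie_encoded_as_ambiguity(self):
        recs = [record("a", "AAAT"), record("b", "AAAC")]
        assert consensus_barcode(recs) == "AAAY"

    def test_identical_sets_flagged(self):
        recs = [
            record("a", "ACGT", species="s1"),
            record("b", "ACGT", species="s2"),
        ]
        _, clashes = consensus_uniqueness(recs)
        assert clashes == [("s1", "s2")]


class TestTreeCriteria:
    @pytest.fixture
    def gapped_library(self):
        records, truth, trees = make_scenario(
            ScenarioConfig(n_species=4, n_individuals=4, preset="clean_gap", seed=5)
        )
        m = distance_matrix(records, 1)
        return records, nj_tree(m)

    def test_monophyletic_species_succeed(self, gapped_library):
        records, tree = gapped_library
        outcomes = tree_id_hebert(tree, records)
        assert {o.verdict for o in outcomes} == {"success"}

    def test_meier_agrees_on_monophyly(self, gapped_library):
        records, tree = gapped_library
        outcomes = tree_id_meier(tree, records)
        assert {o.verdict for o in outcomes} == {"success"}

    def test_singleton_species_ambiguous_under_hebert(self, two_genus_records):
        m = distance_matrix(two_genus_records, 1)
        outcomes = {o.query_id: o for o in tree_id_hebert(nj_tree(m), two_genus_records)}
        assert outcomes["d1"].verdict == "ambiguous"

    def test_two_sequence_species_ambiguous_under_meier(self, two_genus_records):
        m = distance_matrix(two_genus_records, 1)
        outcomes = tree_id_meier(nj_tree(m), two_genus_records)
        assert {o.verdict for o in outcomes} == {"ambiguous"}

    def test_tip_mismatch_rejected(self, two_genus_records):
        m = distance_matrix(two_genus_records, 1)
        tree = nj_tree(m)
        with pytest.raises(ValueError):
            tree_id_hebert(tree, two_genus_records[:-1])

    def test_paraphyly_contrast(self):
        # the qualitative signature: strict monophyly marks a species split
        # across clades misidentified; the cluster-membership criterion and
        # the distance criteria still identify it
        records, truth, trees = make_scenario(
            ScenarioConfig(n_species=5, n_individuals=4, preset="paraphyly", seed=2)
        )
        split_sp = truth.diagnostics["paraphyletic_species"]
        m = distance_matrix(records, 1)
        tree = nj_tree(m)
        hebert = {o.query_id: o.verdict for o in tree_id_hebert(tree, records)}
        meier = {o.query_id: o.verdict for o in tree_id_meier(tree, records)}
        split_ids = [r.id for r in records if r.species == split_sp]
        assert all(hebert[i] == "misidentified" for i in split_ids)
        assert all(meier[i] == "success" for i in split_ids)
        for i in split_ids:
            assert best_match(i, m, records).verdict == "success"
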