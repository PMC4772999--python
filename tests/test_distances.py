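import itertools
import math
import random

import numpy as np
import pytest

from barcodekit.distances import (
    distance_matrix,
    divergence_summary,
    global_gap_report,
    inter_specific_distances,
    intra_specific_distances,
    local_gap_table,
    p_distance,
    percentile_threshold,
)
from barcodekit.distances import _gap_from_values

from conftest import record


def random_records(rng, n=8, L=30, n_species=3):
    recs = []
    for i in range(n):
        sp = f"sp{i % n_species}"
        seq = "".join(rng.choice("ACGT") for _ in range(L))
        recs.append(record(f"s{i}", seq, species=sp, genus=f"g{(i % n_species) // 2}"))
    return recs


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("AAAA", "TTTT", 1.0),
            ("AC-GT", "ACTGA", 0.25),  # 4 shared sites, 1 difference
            ("ANGT", "AAGT", 0.0),     # ambiguity drops the site
        ],
    )
    def test_examples(self, a, b, expected):
        assert p_distance(a, b, min_overlap=1) == pytest.approx(expected)

    def test_insufficient_overlap_is_undefined(self):
        assert math.isnan(p_distance("AC--", "--GT", min_overlap=1))
        assert math.isnan(p_distance("ACGT", "ACGT", min_overlap=5))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            p_distance("ACGT", "ACG", 1)

    def test_symmetric_and_equals_hamming_without_gaps(self):
        rng = random.Random(11)
        for _ in range(30):
            L = rng.randint(5, 40)
            a = "".join(rng.choice("ACGT") for _ in range(L))
            b = "".join(rng.choice("ACGT") for _ in range(L))
            d_ab = p_distance(a, b, 1)
            assert d_ab == p_distance(b, a, 1)
            hamming = sum(x != y for x, y in zip(a, b)) / L
            assert d_ab == pytest.approx(hamming)


class TestDistanceMatrix:
    def test_identical_pair_is_zero(self):
        m = distance_matrix([record("a", "ACGT"), record("b", "ACGT")], 1)
        assert m.d[0, 1] == 0.0

    def test_matches_elementwise_p_distance(self):
        rng = random.Random(3)
        recs = random_records(rng)
        m = distance_matrix(recs, 1)
        for i, j in itertools.combinations(range(len(recs)), 2):
            assert m.d[i, j] == pytest.approx(
                p_distance(recs[i].sequence, recs[j].sequence, 1)
            )
            assert m.d[i, j] == m.d[j, i]
        assert np.all(np.diag(m.d) == 0.0)

    def test_low_overlap_pair_flagged_undefined(self):
        recs = [record("a", "AC" + "-" * 8), record("b", "--" + "GTACGTAC")]
        m = distance_matrix(recs, min_overlap=300)
        assert math.isnan(m.d[0, 1])
        assert m.overlap[0, 1] == 0

    def test_requires_two_records(self):
        with pytest.raises(ValueError):
            distance_matrix([record("a", "ACGT")], 1)


class TestDivergenceSummary:
    def test_identical_conspecifics(self):
        recs = [record("a", "ACGT"), record("b", "ACGT")]
        div = divergence_summary(distance_matrix(recs, 1), recs)
        row = div.per_species.iloc[0]
        assert (row["min"], row["mean"], row["max"]) == (0.0, 0.0, 0.0)

    def test_degenerate_genus_of_two_species(self):
        recs = [
            record("a", "AAAA", species="s1", genus="g"),
            record("b", "AAAT", species="s2", genus="g"),
        ]
        div = divergence_summary(distance_matrix(recs, 1), recs)
        row = div.per_genus.iloc[0]
        assert (row["min"], row["mean"], row["max"]) == (0.25, 0.25, 0.25)

    def test_matches_bruteforce_groupwise(self):
        rng = random.Random(5)
        recs = random_records(rng, n=8, n_species=3)
        m = distance_matrix(recs, 1)
        div = divergence_summary(m, recs)
        for _, row in div.per_species.iterrows():
            idx = [i for i, r in enumerate(recs) if r.species == row["species"]]
            vals = [m.d[i, j] for i, j in itertools.combinations(idx, 2)]
            if len(idx) < 2:
                assert math.isnan(row["min"])
            else:
                assert row["min"] == pytest.approx(min(vals))
                assert row["mean"] == pytest.approx(sum(vals) / len(vals))
                assert row["max"] == pytest.approx(max(vals))
        for _, row in div.per_genus.iterrows():
            idx = [i for i, r in enumerate(recs) if r.genus == row["genus"]]
            vals = [
                m.d[i, j]
                for i, j in itertools.combinations(idx, 2)
                if recs[i].species != recs[j].species
            ]
            if vals:
                assert row["max"] == pytest.approx(max(vals))

    def test_singleton_species_undefined(self):
        recs = [
            record("a", "ACGT", species="s1"),
            record("b", "ACGG", species="s1"),
            record("c", "TTTT", species="s2"),
        ]
        div = divergence_summary(distance_matrix(recs, 1), recs)
        row = div.per_species.set_index("species").loc["s2"]
        assert math.isnan(row["min"])


class TestPercentileThreshold:
    def test_constant_sample(self):
        recs = [
            record("a", "ACGTACGTAC"), record("b", "ACGTACGTAT"),
            record("c", "ACGAACGTAC", species="spB"),
            record("d", "ACGAACGTAT", species="spB"),
        ]
        m = distance_matrix(recs, 1)
        for q in (5, 50, 95, 100):
            assert percentile_threshold(m, recs, q) == pytest.approx(0.1)

    def test_matches_sorted_list_interpolation(self):
        recs = [record(f"s{i}", "A" * (10 - i) + "T" * i) for i in range(11)]
        m = distance_matrix(recs, 1)
        vals = sorted(intra_specific_distances(m, recs))

        def interp_percentile(sorted_vals, q):
            h = (len(sorted_vals) - 1) * q / 100.0
            lo, hi = int(math.floor(h)), int(math.ceil(h))
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        for q in (50, 90, 95):
            assert percentile_threshold(m, recs, q) == pytest.approx(
                interp_percentile(vals, q)
            )

    def test_monotone_in_q(self):
        rng = random.Random(9)
        recs = random_records(rng, n=9, n_species=3)
        m = distance_matrix(recs, 1)
        qs = [5, 25, 50, 75, 90, 95, 100]
        vals = [percentile_threshold(m, recs, q) for q in qs]
        assert vals == sorted(vals)
        assert vals[-1] == pytest.approx(max(intra_specific_distances(m, recs)))

    def test_no_intra_pairs_rejected(self):
        recs = [record("a", "AAAA", species="s1"), record("b", "TTTT", species="s2")]
        with pytest.raises(ValueError):
            percentile_threshold(distance_matrix(recs, 1), recs)


class TestGlobalGap:
    def test_printed_overlap_width_arithmetic(self):
        # interval bounds straight from the published totals
        rep = _gap_from_values(
            intra=np.array([0.0, 0.0704, 0.1710]),
            inter=np.array([0.0313, 0.1850, 0.2415]),
            grouping="species", group=None, bin_width=0.01, trim=0.0,
        )
        assert rep.overlap_interval == (0.0313, 0.1710)
        assert rep.overlap_width == pytest.approx(0.1397)
        assert not rep.global_gap_present

    def test_disjoint_ranges_show_gap(self):
        rep = _gap_from_values(
            intra=np.array([0.01, 0.05]), inter=np.array([0.09, 0.2]),
            grouping="species", group=None, bin_width=0.01, trim=0.0,
        )
        assert rep.overlap_width == 0.0
        assert rep.global_gap_present

    def test_overlap_fraction_matches_bruteforce(self):
        rng = random.Random(13)
        recs = random_records(rng, n=9, n_species=3)
        m = distance_matrix(recs, 1)
        (rep,) = global_gap_report(m, recs, grouping="species")
        pooled = np.concatenate(
            [intra_specific_distances(m, recs),
             inter_specific_distances(m, recs, "all")]
        )
        lo, hi = rep.overlap_interval
        if rep.overlap_width > 0:
            expected = np.mean((pooled >= lo) & (pooled <= hi))
        else:
            expected = 0.0
        assert rep.overlap_fraction == pytest.approx(float(expected))
        assert rep.intra_hist.sum() == rep.n_intra
        assert rep.inter_hist.sum() == rep.n_inter

    def test_species_grouping_interval_matches_summary(self, two_genus_records):
        m = distance_matrix(two_genus_records, 1)
        (rep,) = global_gap_report(m, two_genus_records)
        intra = intra_specific_distances(m, two_genus_records)
        assert rep.overlap_interval[1] == pytest.approx(float(intra.max()))

    def test_genus_grouping_restricts_comparisons(self, two_genus_records):
        m = distance_matrix(two_genus_records, 1)
        reps = global_gap_report(m, two_genus_records, grouping="genus")
        assert [r.group for r in reps] == ["gA", "gB"]

    def test_trimmed_variant_narrows_interval(self):
        intra = np.concatenate([np.full(50, 0.02), [0.3]])
        inter = np.concatenate([[0.01], np.full(50, 0.2)])
        full = _gap_from_values(intra, inter, "species", None, 0.01, 0.0)
        trimmed = _gap_from_values(intra, inter, "species", None, 0.01, 0.05)
        assert trimmed.overlap_width < full.overlap_width


class TestLocalGap:
    def test_gap_orderings(self):
        rows = local_gap_table(
            distance_matrix(
                [
                    record("a1", "AAAAAAAAAA", species="A"),
                    record("a2", "AAAAAAAAAT", species="A"),
                    record("b1", "TTTTTAAAAA", species="B"),
                    record("b2", "TTTTTAAAAT", species="B"),
                ],
                1,
            ),
            [
                record("a1", "AAAAAAAAAA", species="A"),
                record("a2", "AAAAAAAAAT", species="A"),
                record("b1", "TTTTTAAAAA", species="B"),
                record("b2", "TTTTTAAAAT", species="B"),
            ],
        )
        by_sp = {r.species: r for r in rows}
        assert by_sp["A"].max_intra == pytest.approx(0.1)
        assert by_sp["A"].nn_dist == pytest.approx(0.5)
        assert by_sp["A"].local_gap_present

    def test_singletons_omitted(self, two_genus_records):
        rows = local_gap_table(
            distance_matrix(two_genus_records, 1), two_genus_records
        )
        assert {r.species for r in rows} == {"spA", "spB", "spC"}  # spD singleton

    def test_matches_bruteforce_scan(self):
        rng = random.Random(17)
        recs = random_records(rng, n=10, n_species=4)
        m = distance_matrix(recs, 1)
        rows = {r.species: r for r in local_gap_table(m, recs)}
        for sp in {r.species for r in recs}:
            idx = [i for i, r in enumerate(recs) if r.species == sp]
            others = [i for i, r in enumerate(recs) if r.species != sp]
            if len(idx) < 2:
                assert sp not in rows
                continue
            max_intra = max(
                m.d[i, j] for i, j in itertools.combinations(idx, 2)
            )
            nn = min(m.d[i, j] for i in idx for j in others)
            assert rows[sp].max_intra == pytest.approx(max_intra)
            assert rows[sp].nn_dist == pytest.approx(nn)
            assert rows[sp].local_gap_present == (max_intra < nn)
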