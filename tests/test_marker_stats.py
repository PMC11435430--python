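import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pearsnp import (
    MISSING,
    PopulationAssignment,
    allele_frequencies,
    allelic_richness,
    core_candidate_gate,
    diversity_table,
    expected_het_unbiased,
    filter_loci,
    locus_stats_frame,
    pic,
)
from _oracles import allelic_richness_enumeration


class TestPic:
    def test_known_values(self):
        assert pic([0.5, 0.5]) == pytest.approx(0.375, abs=1e-12)
        assert pic([1.0, 0.0]) == pytest.approx(0.0, abs=1e-12)
        # hand evaluation: 1 - (0.81 + 0.01) - 2*0.81*0.01
        assert pic([0.9, 0.1]) == pytest.approx(1 - 0.82 - 0.0162, abs=1e-12)

    def test_rejects_invalid_frequency_vectors(self):
        with pytest.raises(ValueError):
            pic([0.6, 0.6])
        with pytest.raises(ValueError):
            pic([-0.1, 1.1])

    @settings(max_examples=50, derandomize=True)
    @given(
        st.floats(min_value=1e-6, max_value=0.5),
        st.floats(min_value=1e-6, max_value=0.5),
    )
    def test_strictly_increasing_in_maf(self, x, y):
        """For biallelic loci PIC rises monotonically with MAF on (0, 0.5]."""
        lo, hi = sorted((x, y))
        if hi - lo < 1e-9:
            return
        assert pic([lo, 1 - lo]) < pic([hi, 1 - hi])

    def test_multiallelic_formula(self):
        # 3 equifrequent alleles: 1 - 3/9 - 2*3*(1/81)
        p = [1 / 3] * 3
        expected = 1 - 1 / 3 - 2 * 3 * (1 / 9) ** 2
        assert pic(p) == pytest.approx(expected, abs=1e-12)


class TestExpectedHet:
    def test_closed_form_small_sample(self):
        assert expected_het_unbiased([0.5, 0.5], 5) == pytest.approx(
            0.5 * 10 / 9, abs=1e-12
        )

    def test_fixed_locus_and_limit(self):
        assert expected_het_unbiased([1.0, 0.0], 7) == 0.0
        assert expected_het_unbiased([0.5, 0.5], 10**7) == pytest.approx(0.5, abs=1e-6)

    def test_exceeds_plug_in_diversity(self):
        for p in (0.1, 0.3, 0.5):
            plug_in = 1 - p**2 - (1 - p) ** 2
            assert expected_het_unbiased([p, 1 - p], 8) > plug_in

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            expected_het_unbiased([0.5, 0.5], 1)


class TestAlleleFrequencies:
    def test_counting_over_diploid_calls(self, make_matrix):
        matrix = make_matrix([[0], [1], [2]])
        assert allele_frequencies(matrix, "m000") == pytest.approx((0.5, 0.5))

    def test_monomorphic(self, make_matrix):
        matrix = make_matrix([[0], [0], [0]])
        assert allele_frequencies(matrix, "m000") == pytest.approx((1.0, 0.0))

    def test_missing_excluded(self, make_matrix):
        matrix = make_matrix([[1], [MISSING]])
        assert allele_frequencies(matrix, "m000") == pytest.approx((0.5, 0.5))

    def test_all_missing_sentinel_and_unknown_marker(self, make_matrix):
        matrix = make_matrix([[MISSING], [MISSING]])
        p_ref, p_alt = allele_frequencies(matrix, "m000")
        assert np.isnan(p_ref) and np.isnan(p_alt)
        with pytest.raises(KeyError):
            allele_frequencies(matrix, "nope")

    def test_subset_restriction(self, make_matrix):
        matrix = make_matrix([[0], [2], [2]])
        assert allele_frequencies(matrix, "m000", subset=["acc00", "acc01"]) == (
            pytest.approx((0.5, 0.5))
        )


class TestAllelicRichness:
    def _one_locus_pop(self, make_matrix, calls):
        matrix = make_matrix([[c] for c in calls])
        pops = PopulationAssignment(mapping={a: "P" for a in matrix.accessions})
        return matrix, pops

    def test_monomorphic_locus_gives_one(self, make_matrix):
        matrix, pops = self._one_locus_pop(make_matrix, [0, 0, 0, 0])
        assert allelic_richness(matrix, pops, g=4)["P"] == pytest.approx(1.0)

    def test_balanced_locus_full_sample_gives_two(self, make_matrix):
        matrix, pops = self._one_locus_pop(make_matrix, [0, 0, 2, 2])
        assert allelic_richness(matrix, pops, g=8)["P"] == pytest.approx(2.0)

    def test_matches_exhaustive_enumeration(self, make_matrix):
        """10 diploids, 18 REF / 2 ALT gene copies, rarefied to g=10."""
        calls = [0] * 8 + [1, 1]
        matrix, pops = self._one_locus_pop(make_matrix, calls)
        expected = allelic_richness_enumeration(18, 2, 10)
        assert allelic_richness(matrix, pops, g=10)["P"] == pytest.approx(
            expected, abs=1e-10
        )

    def test_pair_sampling_identity_at_g2(self, make_matrix):
        """A(g=2) equals the direct two-draw formula."""
        calls = [0] * 6 + [1] * 3 + [2]
        matrix, pops = self._one_locus_pop(make_matrix, calls)
        n_ref, n_alt, total = 15, 5, 20
        from math import comb

        direct = (1 - comb(total - n_ref, 2) / comb(total, 2)) + (
            1 - comb(total - n_alt, 2) / comb(total, 2)
        )
        assert allelic_richness(matrix, pops, g=2)["P"] == pytest.approx(
            direct, abs=1e-12
        )

    def test_invalid_g_rejected(self, make_matrix):
        matrix, pops = self._one_locus_pop(make_matrix, [0, 1, 2])
        with pytest.raises(ValueError):
            allelic_richness(matrix, pops, g=7)


class TestFilterLoci:
    def test_constructed_fixture_counts(self, make_matrix):
        """10 loci; 2 at MAF 0.02 and 1 at 40% missing leave 7 survivors."""
        rng = np.random.default_rng(0)
        n = 50
        calls = rng.integers(0, 3, size=(n, 10)).astype(np.int8)
        # loci 0-1: two ALT-carrying accessions among 50 -> MAF 0.02
        for k in (0, 1):
            calls[:, k] = 0
            calls[:2, k] = 1
        # locus 2: 40% missing
        calls[:, 2] = rng.integers(0, 3, size=n)
        calls[: int(0.4 * n), 2] = MISSING
        matrix = make_matrix(calls)
        filtered, report = filter_loci(matrix, maf_min=0.05, missing_max=0.15)
        assert report.n_input == 10
        assert report.n_dropped_missing == 1
        assert report.n_dropped_maf == 2
        assert filtered.n_loci == 7
        assert report.n_retained + report.n_dropped_missing + report.n_dropped_maf == 10

    def test_extreme_thresholds_are_identity(self, make_matrix):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(30, 12)).astype(np.int8)
        matrix = make_matrix(calls)
        filtered, _ = filter_loci(matrix, maf_min=0.0, missing_max=1.01, depth_min=0)
        assert filtered.marker_ids == matrix.marker_ids
        np.testing.assert_array_equal(filtered.calls, matrix.calls)

    def test_depth_masking_precedes_missing_rate(self, make_matrix):
        """Calls below minimum depth become missing before rates are taken."""
        calls = np.array([[0, 0], [1, 1], [2, 2], [0, 1], [1, 0]], dtype=np.int8)
        depth = np.full_like(calls, 30, dtype=np.int32)
        depth[:4, 0] = 2  # locus 0: 4/5 calls under-covered -> 80% missing
        matrix = make_matrix(calls, depth=depth)
        filtered, report = filter_loci(matrix, maf_min=0.0, missing_max=0.5, depth_min=3)
        assert report.n_depth_masked_calls == 4
        assert report.dropped_missing == ["m000"]
        assert filtered.marker_ids == ["m001"]

    def test_no_depth_information_warns_and_skips_rule(self, make_matrix):
        matrix = make_matrix(np.random.default_rng(2).integers(0, 3, (20, 5)))
        with pytest.warns(UserWarning, match="no depth"):
            filtered, report = filter_loci(matrix, maf_min=0.0, missing_max=1.01)
        assert report.n_depth_masked_calls == 0
        assert filtered.n_loci == 5

    def test_idempotent(self, small_collection):
        matrix, _, _ = small_collection
        once, _ = filter_loci(matrix)
        twice, report2 = filter_loci(once)
        assert twice.marker_ids == once.marker_ids
        np.testing.assert_array_equal(twice.calls, once.calls)
        assert report2.n_retained == once.n_loci


class TestCandidateGate:
    def test_strict_inequalities_at_thresholds(self):
        stats = pd.DataFrame(
            {
                "marker_id": ["a", "b", "c", "d"],
                "pic": [0.25, 0.30, 0.30, 0.26],
                "het_rate": [0.10, 0.40, 0.35, 0.34],
            }
        )
        assert core_candidate_gate(stats, pic_min=0.25, het_max=0.35) == ["d"]

    def test_membership_matches_hand_enumeration(self):
        rng = np.random.default_rng(3)
        stats = pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(20)],
                "pic": rng.uniform(0, 0.375, 20),
                "het_rate": rng.uniform(0, 0.6, 20),
            }
        )
        expected = [
            row.marker_id
            for row in stats.itertuples()
            if row.pic > 0.25 and row.het_rate < 0.35
        ]
        assert core_candidate_gate(stats) == expected


def test_locus_stats_invariants(small_collection):
    matrix, _, _ = small_collection
    stats = locus_stats_frame(matrix)
    assert (stats["maf"].dropna() <= 0.5 + 1e-12).all()
    assert (stats["pic"].dropna() <= 0.375 + 1e-12).all()
    np.testing.assert_allclose(
        stats["missing_rate"], 1 - stats["n_called"] / matrix.n_accessions
    )
    assert (stats["he_unbiased"].dropna() >= 0).all()


def test_diversity_table_tracks_drift_ordering(small_collection):
    """The weakly drifted population keeps more diversity than the strongly
    drifted one, on every reported statistic."""
    matrix, pops, params = small_collection
    table = diversity_table(matrix, pops).set_index("population")
    weak = params.labels[int(np.argmin(params.divergence_F))]
    strong = params.labels[int(np.argmax(params.divergence_F))]
    for col in ("A", "He", "PIC"):
        assert table.loc[weak, col] > table.loc[strong, col]
    assert "Total" in table.index
    assert table["sample_size"]["Total"] == matrix.n_accessions
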