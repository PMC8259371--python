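import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyomorph.errors import KaryomorphError, MeasurementError
from karyomorph.karyomorphometry import (
    chromosome_stats,
    classify_levan,
    clr,
    cv_cl,
    cv_ci,
    karyotype_formula,
    m_ca,
    match_homolog_indices,
    mean_karyotype,
    pair_homologs,
    stebbins_class,
    summarize_accession,
    summarize_karyotype,
    thcl,
    total_pairing_cost,
)

from conftest import make_dataset, make_karyotype, make_plate


class TestChromosomeStats:
    def test_perfect_metacentric(self):
        s = chromosome_stats(2.0, 2.0)
        assert (s.cl, s.ci, s.r, s.levan_class) == (4.0, 50.0, 1.0, "m")

    def test_exact_arithmetic(self):
        s = chromosome_stats(1.0, 3.0)
        assert (s.cl, s.ci, s.r) == (4.0, 25.0, 3.0)

    def test_boundary_ratio(self):
        s = chromosome_stats(1.0, 1.7)
        assert round(s.ci, 2) == 37.04
        assert s.r == pytest.approx(1.7)
        assert s.levan_class == "m"

    def test_errors(self):
        with pytest.raises(MeasurementError):
            chromosome_stats(3.0, 2.0)
        with pytest.raises(MeasurementError):
            chromosome_stats(0.0, 2.0)


class TestClassifyLevan:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (1.0, "m"),
            (1.7, "m"),
            (1.7000001, "sm"),
            (3.0, "sm"),
            (5.0, "st"),
            (7.0, "st"),
            (7.000001, "t"),
            (50.0, "t"),
        ],
    )
    def test_intervals_and_boundaries(self, r, expected):
        assert classify_levan(r) == expected

    def test_below_one_rejected(self):
        with pytest.raises(KaryomorphError):
            classify_levan(0.9)


def brute_force_matching(plate):
    """Enumerate all (2n-1)!! perfect matchings; return the cheapest cost."""
    stats = [chromosome_stats(m.p, m.q) for m in plate.measurements]

    def matchings(indices):
        if not indices:
            yield []
            return
        first, rest = indices[0], indices[1:]
        for k, partner in enumerate(rest):
            for tail in matchings(rest[:k] + rest[k + 1 :]):
                yield [(first, partner)] + tail

    return min(
        total_pairing_cost(stats, pairing)
        for pairing in matchings(tuple(range(len(stats))))
    )


class TestPairHomologs:
    def test_exact_duplicates_recovered(self):
        arms = [(1.0, 2.0), (1.5, 2.5), (1.0, 3.0)]
        plate = make_plate(arms + arms)
        complement = pair_homologs(plate)
        assert sorted((c.p, c.q) for c in complement) == sorted(arms)

    def test_odd_count_rejected(self):
        with pytest.raises(MeasurementError, match="odd"):
            pair_homologs(make_plate([(1, 2), (1, 2), (1, 2)]))

    def test_same_length_different_ci_not_mixed(self):
        # two pairs of identical total length, CI 50 vs 30
        plate = make_plate([(2.0, 2.0), (1.2, 2.8), (2.0, 2.0), (1.2, 2.8)])
        complement = pair_homologs(plate)
        assert sorted(round(c.ci, 6) for c in complement) == [30.0, 50.0]

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_matches_exhaustive_minimum_cost(self, n, seed):
        rng = np.random.default_rng(seed)
        arms = []
        for _ in range(n):
            p, q = sorted(rng.uniform(0.5, 3.0, size=2))
            for _ in range(2):
                arms.append((p * rng.lognormal(0, 0.05), q * rng.lognormal(0, 0.05)))
        plate = make_plate([(min(a, b), max(a, b)) for a, b in arms])
        stats = [chromosome_stats(m.p, m.q) for m in plate.measurements]
        pairs = match_homolog_indices(plate)
        assert total_pairing_cost(stats, pairs) == pytest.approx(
            brute_force_matching(plate), abs=1e-12
        )


class TestMeanKaryotype:
    def test_single_plate_identity(self):
        arms = [(1.0, 2.0), (1.5, 2.5)]
        dataset = make_dataset([arms + arms])
        karyotype = mean_karyotype(dataset)
        complement = pair_homologs(dataset.plates[0])
        assert karyotype.chromosomes == complement

    def test_condensation_scaling_closed_form(self):
        arms = [(1.0, 2.0), (1.5, 2.5), (1.0, 3.0)]
        scaled = [(1.2 * p, 1.2 * q) for p, q in arms]
        dataset = make_dataset([arms + arms, scaled + scaled])
        karyotype = mean_karyotype(dataset)
        base = sorted(p + q for p, q in arms)[::-1]
        np.testing.assert_allclose([c.cl for c in karyotype.chromosomes],
                                   [1.1 * cl for cl in base])
        base_ci = sorted(100 * p / (p + q) for p, q in arms)
        np.testing.assert_allclose(sorted(c.ci for c in karyotype.chromosomes), base_ci)

    def test_relative_averaging_removes_condensation(self):
        arms = [(1.0, 2.0), (1.5, 2.5), (1.0, 3.0)]
        scaled = [(1.2 * p, 1.2 * q) for p, q in arms]
        dataset = make_dataset([arms + arms, scaled + scaled])
        karyotype = mean_karyotype(dataset, averaging="relative")
        base = sorted(p + q for p, q in arms)[::-1]
        np.testing.assert_allclose([c.cl for c in karyotype.chromosomes],
                                   [1.1 * cl for cl in base])
        # relative CVs equal those of a single plate
        assert cv_cl(karyotype) == pytest.approx(
            cv_cl(mean_karyotype(make_dataset([arms + arms]))))

    def test_empty_dataset_rejected(self):
        dataset = make_dataset([[(1, 2), (1, 2)]])
        empty = type(dataset)(dataset.accession_id, dataset.two_n, ())
        with pytest.raises(MeasurementError, match="no plates"):
            mean_karyotype(empty)


class TestKaryotypeFormulaOp:
    def test_all_metacentric(self):
        karyotype = make_karyotype([(1.0, 1.0)] * 9)
        assert str(karyotype_formula(karyotype)) == "9m"

    def test_mixed_rendering(self):
        karyotype = make_karyotype([(1.0, 1.2)] * 2 + [(1.0, 2.0)] * 8)
        kf = karyotype_formula(karyotype)
        assert kf.counts == {"m": 2, "sm": 8}
        assert str(kf) == "2m + 8sm"

    def test_counts_sum_to_n(self):
        karyotype = make_karyotype([(1.0, 1.0), (1.0, 2.0), (0.5, 3.0), (0.2, 2.0)])
        assert karyotype_formula(karyotype).n == karyotype.n


class TestLengthStatistics:
    def test_thcl_and_clr(self):
        karyotype = make_karyotype([(2.0, 2.0), (1.5, 1.5), (1.0, 1.0)])
        assert thcl(karyotype) == pytest.approx(9.0)
        assert clr(karyotype) == (pytest.approx(2.0), pytest.approx(4.0))

    def test_thcl_conservation_through_pairing(self):
        rng = np.random.default_rng(0)
        arms = [tuple(sorted(rng.uniform(0.5, 3.0, 2))) for _ in range(8)]
        plate = make_plate(arms + arms)
        total = sum(m.p + m.q for m in plate.measurements)
        complement = pair_homologs(plate)
        assert sum(c.cl for c in complement) == pytest.approx(total / 2)

    def test_cv_cl_hand_value(self):
        karyotype = make_karyotype([(1.0, 1.0), (2.0, 2.0)])
        assert cv_cl(karyotype) == pytest.approx(47.14, abs=0.005)

    def test_cv_cl_zero_for_equal_lengths(self):
        karyotype = make_karyotype([(1.0, 1.0)] * 5)
        assert cv_cl(karyotype) == 0.0

    def test_cv_ci_hand_value(self):
        # CI values 50 and 25
        karyotype = make_karyotype([(2.0, 2.0), (1.0, 3.0)])
        assert cv_ci(karyotype) == pytest.approx(47.14, abs=0.005)

    def test_population_sd_option(self):
        karyotype = make_karyotype([(1.0, 1.0), (2.0, 2.0)])
        assert cv_cl(karyotype, sd="population") == pytest.approx(100 / 3, abs=1e-9)

    def test_cv_requires_two(self):
        with pytest.raises(KaryomorphError):
            cv_cl(make_karyotype([(1.0, 2.0)]))

    def test_m_ca_zero_for_metacentrics(self):
        assert m_ca(make_karyotype([(1.0, 1.0)] * 4)) == 0.0

    def test_m_ca_single_chromosome(self):
        assert m_ca(make_karyotype([(1.0, 3.0)])) == pytest.approx(50.0)

    @given(
        st.lists(
            st.tuples(
                st.floats(0.1, 10.0, allow_nan=False),
                st.floats(0.1, 10.0, allow_nan=False),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_m_ca_bounds(self, arms):
        value = m_ca(make_karyotype(arms))
        assert 0.0 <= value < 100.0


class TestStebbins:
    def test_fully_symmetric(self):
        assert stebbins_class(make_karyotype([(1.0, 1.0)] * 5)) == "1A"

    def test_3a_pattern(self):
        # length ratio 1.9, 5 of 9 chromosomes with arm ratio > 2
        lengths = np.linspace(1.9, 1.0, 9)
        arms = []
        for i, cl in enumerate(lengths):
            r = 2.5 if i < 5 else 1.5
            arms.append((cl / (1 + r), cl * r / (1 + r)))
        assert stebbins_class(make_karyotype(arms)) == "3A"

    def test_2a_pattern(self):
        # length ratio 1.8, 3 of 9 with arm ratio > 2
        lengths = np.linspace(1.8, 1.0, 9)
        arms = []
        for i, cl in enumerate(lengths):
            r = 2.5 if i < 3 else 1.5
            arms.append((cl / (1 + r), cl * r / (1 + r)))
        assert stebbins_class(make_karyotype(arms)) == "2A"

    @pytest.mark.parametrize(
        "length_ratio,expected_letter", [(1.5, "A"), (2.0, "B"), (4.0, "B"), (4.5, "C")]
    )
    def test_letter_thresholds(self, length_ratio, expected_letter):
        arms = [(length_ratio / 2, length_ratio / 2), (0.5, 0.5)]
        assert stebbins_class(make_karyotype(arms))[1] == expected_letter

    def test_row_four_when_all_asymmetric(self):
        assert stebbins_class(make_karyotype([(1.0, 3.0)] * 4)).startswith("4")


class TestSummarize:
    def test_single_plate_equals_direct(self):
        arms = [(1.0, 2.0), (1.5, 2.5), (0.8, 2.9)]
        dataset = make_dataset([arms + arms])
        summary = summarize_accession(dataset)
        direct = summarize_karyotype(mean_karyotype(dataset))
        assert summary == direct

    def test_summary_consistency(self):
        arms = [(1.0, 2.0), (1.5, 2.5), (0.8, 2.9)]
        dataset = make_dataset([arms + arms, arms + arms])
        summary = summarize_accession(dataset)
        assert summary.kf.n == 3
        assert summary.thcl >= summary.clr_max
        assert summary.clr_min <= summary.clr_max


class TestInvariances:
    ARMS = [(1.0, 2.0), (1.5, 2.5), (0.8, 2.9), (1.1, 1.2)]

    @given(st.floats(0.05, 20.0, allow_nan=False))
    def test_scale_invariance(self, c):
        base = make_karyotype(self.ARMS)
        scaled = make_karyotype([(c * p, c * q) for p, q in self.ARMS])
        assert cv_cl(scaled) == pytest.approx(cv_cl(base), rel=1e-9)
        assert cv_ci(scaled) == pytest.approx(cv_ci(base), rel=1e-9)
        assert m_ca(scaled) == pytest.approx(m_ca(base), rel=1e-9)
        assert stebbins_class(scaled) == stebbins_class(base)
        assert karyotype_formula(scaled) == karyotype_formula(base)
        assert thcl(scaled) == pytest.approx(c * thcl(base), rel=1e-9)
        np.testing.assert_allclose(clr(scaled), np.array(clr(base)) * c, rtol=1e-9)

    @settings(max_examples=25)
    @given(st.permutations(list(range(8))))
    def test_permutation_invariance(self, order):
        arms = self.ARMS + self.ARMS
        plate_a = make_plate(arms)
        plate_b = make_plate([arms[i] for i in order])
        dataset_a = make_dataset([[arms[i] for i in range(8)]])
        dataset_b = make_dataset([[arms[i] for i in order]])
        assert summarize_accession(dataset_a) == summarize_accession(dataset_b)
        assert pair_homologs(plate_a) == pair_homologs(plate_b)
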