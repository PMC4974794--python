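import numpy as np
import pytest

from kalpha import (
    DegenerateDataWarning,
    EstimationError,
    NOMINAL,
    ORDINAL,
    RatingTable,
    alpha_from_ratings,
    coincidence_matrix,
    count_matrix,
    delta_matrix,
    fleiss_k,
    fleiss_k_from_ratings,
    fleiss_k_se,
    krippendorff_alpha,
    ordinal_delta,
)
from kalpha.ratings import CategoryCounts

from reference import (
    alpha_bruteforce,
    coincidence_bruteforce,
    fleiss_k_bruteforce,
    fleiss_se_transcription,
    pairwise_mean_agreement,
    random_table,
)


class TestFleissK:
    def test_worked_example_components_and_value(self, worked_table):
        est = fleiss_k_from_ratings(worked_table)
        comp = est.components
        assert comp.mean_agreement == pytest.approx(0.75)
        np.testing.assert_allclose(comp.marginal_props, [0.625, 0.375])
        assert comp.chance_agreement == pytest.approx(0.53125)
        assert est.value == pytest.approx(0.466667, abs=5e-7)
        assert est.n_subjects_used == 4 and not est.degenerate_flag

    def test_perfect_agreement_gives_one(self, perfect_table):
        assert fleiss_k_from_ratings(perfect_table).value == pytest.approx(1.0)

    def test_systematic_two_rater_disagreement_gives_minus_one(self, inverse_table):
        assert fleiss_k_from_ratings(inverse_table).value == pytest.approx(-1.0)

    def test_incomplete_subjects_are_dropped(self):
        values = np.array([[1, 1, 0], [1, 1, 1], [2, 2, 2], [1, 2, 1]])
        est = fleiss_k(count_matrix(RatingTable(values=values, k=2)))
        assert est.n_subjects_used == 3
        complete_only = RatingTable(values=values[1:], k=2)
        assert est.value == pytest.approx(fleiss_k_from_ratings(complete_only).value)

    def test_fewer_than_two_complete_cases_is_an_error(self):
        values = np.array([[1, 0], [0, 2], [1, 1]])
        with pytest.raises(EstimationError) as err:
            fleiss_k(count_matrix(RatingTable(values=values, k=2)))
        assert err.value.n_subjects_used == 1

    def test_single_category_everywhere_is_degenerate_one(self):
        table = RatingTable(values=np.ones((5, 3), dtype=int), k=2)
        with pytest.warns(DegenerateDataWarning):
            est = fleiss_k_from_ratings(table)
        assert est.value == 1.0 and est.degenerate_flag

    def test_mean_agreement_matches_pairwise_loop_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = random_table(rng, 25, 4, 3, missing_frac=0.1)
            counts = count_matrix(RatingTable(values=values, k=3))
            try:
                est = fleiss_k(counts)
            except EstimationError:
                continue
            assert est.components.mean_agreement == pytest.approx(
                pairwise_mean_agreement(values), abs=1e-12
            )
            assert est.value == pytest.approx(fleiss_k_bruteforce(values, 3), abs=1e-12)

    def test_agrees_with_statsmodels_on_complete_tables(self):
        from statsmodels.stats.inter_rater import fleiss_kappa

        rng = np.random.default_rng(5)
        for _ in range(10):
            values = random_table(rng, 30, 5, 4)
            counts = count_matrix(RatingTable(values=values, k=4))
            ours = fleiss_k(counts).value
            theirs = fleiss_kappa(counts.counts, method="fleiss")
            assert ours == pytest.approx(theirs, abs=1e-12)


class TestFleissSE:
    def test_balanced_binary_case_simplifies_to_sqrt_term(self):
        # p = (0.5, 0.5) makes the correction factor exactly 1
        counts = CategoryCounts(
            counts=np.vstack([np.tile([3, 2], (50, 1)), np.tile([2, 3], (50, 1))]),
            n_raters=5,
        )
        assert fleiss_k_se(counts) == pytest.approx(np.sqrt(2.0 / 2000.0), abs=1e-12)

    def test_scales_inversely_with_sqrt_n_subjects(self):
        block = np.tile([3, 1], (40, 1))
        se_small = fleiss_k_se(CategoryCounts(counts=block, n_raters=4))
        se_large = fleiss_k_se(CategoryCounts(counts=np.tile(block, (2, 1)), n_raters=4))
        assert se_large == pytest.approx(se_small / np.sqrt(2.0), rel=1e-12)

    def test_matches_independent_transcription_on_random_counts(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            values = random_table(rng, 40, 5, 3, missing_frac=0.05)
            counts = count_matrix(RatingTable(values=values, k=3))
            assert fleiss_k_se(counts) == pytest.approx(
                fleiss_se_transcription(counts.counts, 5), abs=1e-12
            )

    def test_single_used_category_is_an_error(self):
        counts = CategoryCounts(counts=np.tile([3, 0], (10, 1)), n_raters=3)
        with pytest.raises(EstimationError):
            fleiss_k_se(counts)


class TestCoincidenceMatrix:
    def test_worked_example_matrix_marginals_and_total(self, worked_table):
        coinc = coincidence_matrix(count_matrix(worked_table))
        np.testing.assert_allclose(coinc.o, [[4.0, 1.0], [1.0, 2.0]])
        np.testing.assert_allclose(coinc.marginals, [5.0, 3.0])
        assert coinc.grand_total == pytest.approx(8.0)
        assert coinc.excluded_units == 0

    def test_single_rating_subject_excluded(self):
        values = np.array([[1, 0], [1, 2], [2, 2]])
        coinc = coincidence_matrix(count_matrix(RatingTable(values=values, k=2)))
        assert coinc.excluded_units == 1
        assert coinc.grand_total == pytest.approx(4.0)

    def test_complete_data_total_is_n_times_raters(self):
        rng = np.random.default_rng(21)
        values = random_table(rng, 30, 4, 3)
        coinc = coincidence_matrix(count_matrix(RatingTable(values=values, k=3)))
        assert coinc.grand_total == pytest.approx(120.0)

    def test_matches_ordered_pair_enumeration_with_missing(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            values = random_table(rng, 20, 4, 3, missing_frac=0.25)
            counts = count_matrix(RatingTable(values=values, k=3))
            if not (counts.row_totals >= 2).any():
                continue
            coinc = coincidence_matrix(counts)
            np.testing.assert_allclose(
                coinc.o, coincidence_bruteforce(values, 3), atol=1e-12
            )
            assert np.allclose(coinc.o, coinc.o.T)
            assert (coinc.o >= 0).all()


class TestDistanceMetrics:
    @pytest.mark.parametrize(
        "c, cp, expected", [(1, 3, 25.0), (1, 2, 9.0), (2, 2, 0.0), (3, 1, 25.0)]
    )
    def test_ordinal_delta_cumulative_formula(self, c, cp, expected):
        assert ordinal_delta(c, cp, (4, 2, 2)) == pytest.approx(expected)

    def test_delta_matrix_symmetric_with_zero_diagonal(self):
        for kind in ("nominal", "ordinal"):
            d = delta_matrix(kind, np.array([4.0, 2.0, 2.0]))
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0.0)
            assert (d >= 0).all()


class TestKrippendorffAlpha:
    def test_worked_example_value_and_disagreements(self, worked_table):
        est = alpha_from_ratings(worked_table)
        d_o, d_e = est.components
        assert d_o == pytest.approx(0.25)
        assert d_e == pytest.approx(30.0 / 56.0)
        assert est.value == pytest.approx(0.533333, abs=5e-7)

    def test_perfect_agreement_gives_one(self, perfect_table):
        assert alpha_from_ratings(perfect_table).value == pytest.approx(1.0)

    def test_complete_nominal_identity_with_fleiss_k(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            values = random_table(rng, 20, 3, 3, agreement=rng.random())
            table = RatingTable(values=values, k=3)
            k_hat = fleiss_k_from_ratings(table).value
            a_hat = alpha_from_ratings(table).value
            n_tot = 60
            assert 1 - a_hat == pytest.approx((1 - k_hat) * (n_tot - 1) / n_tot, abs=1e-10)

    def test_matches_bruteforce_with_missing_nominal_and_ordinal(self):
        rng = np.random.default_rng(23)
        for kind, metric in (("nominal", NOMINAL), ("ordinal", ORDINAL)):
            for _ in range(10):
                values = random_table(rng, 25, 4, 4, missing_frac=0.2)
                table = RatingTable(values=values, k=4)
                est = alpha_from_ratings(table, metric)
                assert est.value == pytest.approx(
                    alpha_bruteforce(values, 4, kind), abs=1e-10
                )

    def test_single_category_everywhere_is_degenerate_one(self):
        table = RatingTable(values=np.full((4, 3), 2, dtype=int), k=3)
        with pytest.warns(DegenerateDataWarning):
            est = alpha_from_ratings(table)
        assert est.value == 1.0 and est.degenerate_flag

    def test_no_pairable_subject_is_an_error(self):
        values = np.array([[1, 0, 0], [0, 2, 0]])
        with pytest.raises(EstimationError):
            alpha_from_ratings(RatingTable(values=values, k=2))

    def test_ordinal_alpha_exceeds_nominal_on_adjacent_rank_disagreements(self):
        rng = np.random.default_rng(29)
        latent = rng.integers(1, 5, size=50)
        shift = rng.choice([-1, 0, 0, 1], size=(50, 4))
        values = np.clip(latent[:, None] + shift, 1, 4)
        table = RatingTable(values=values, k=4)
        nominal = alpha_from_ratings(table, NOMINAL).value
        ordinal = alpha_from_ratings(table, ORDINAL).value
        assert ordinal > nominal
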