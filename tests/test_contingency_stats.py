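import numpy as np
import pytest

from msapkit.contingency_stats import (
    ContingencyTable,
    adjusted_residuals,
    level_by_treatment_table,
    likelihood_ratio_test,
    pearson_chi_square,
)
from msapkit.errors import DegenerateTableError
from msapkit.msap_core import BandTypeCounts


def hand_pearson(counts):
    counts = np.asarray(counts, float)
    n = counts.sum()
    expected = np.outer(counts.sum(1), counts.sum(0)) / n
    return ((counts - expected) ** 2 / expected).sum()


def hand_g(counts):
    counts = np.asarray(counts, float)
    n = counts.sum()
    expected = np.outer(counts.sum(1), counts.sum(0)) / n
    mask = counts > 0
    return 2.0 * (counts[mask] * np.log(counts[mask] / expected[mask])).sum()


def hand_adjusted_residuals(counts):
    counts = np.asarray(counts, float)
    n = counts.sum()
    expected = np.outer(counts.sum(1), counts.sum(0)) / n
    rf, cf = counts.sum(1) / n, counts.sum(0) / n
    return (counts - expected) / np.sqrt(
        expected * (1 - rf)[:, None] * (1 - cf)[None, :])


def random_tables(n_tables, seed, shape_max=4, cell_max=60):
    rng = np.random.default_rng(seed)
    while n_tables:
        r, c = rng.integers(2, shape_max + 1, size=2)
        counts = rng.integers(1, cell_max, size=(r, c))
        yield counts
        n_tables -= 1


def test_proportional_table_gives_zero_statistic_p_one():
    table = ContingencyTable([[10, 10], [10, 10]])
    for test in (pearson_chi_square, likelihood_ratio_test):
        res = test(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
    assert np.allclose(adjusted_residuals(table).residuals, 0.0, atol=1e-12)


def test_statistics_match_hand_formula_oracles():
    for counts in random_tables(50, seed=202):
        table = ContingencyTable(counts)
        assert pearson_chi_square(table).statistic == pytest.approx(
            hand_pearson(counts), abs=1e-10)
        assert likelihood_ratio_test(table).statistic == pytest.approx(
            hand_g(counts), abs=1e-10)
        assert np.allclose(adjusted_residuals(table).residuals,
                           hand_adjusted_residuals(counts), atol=1e-10)


def test_df_and_worked_example():
    table = ContingencyTable([[10, 20], [30, 40]])
    res = pearson_chi_square(table)
    assert res.df == 1
    assert res.statistic == pytest.approx(hand_pearson([[10, 20], [30, 40]]), abs=1e-12)


def test_adjusted_residuals_cross_check_statsmodels():
    import statsmodels.api as sm

    counts = [[665, 789], [201, 113], [768, 733]]
    ours = adjusted_residuals(ContingencyTable(counts)).residuals
    theirs = sm.stats.Table(np.asarray(counts)).standardized_resids
    assert np.allclose(ours, np.asarray(theirs), atol=1e-10)


def test_2x2_adjusted_residuals_all_equal_in_magnitude():
    for counts in random_tables(30, seed=9, shape_max=2):
        resid = adjusted_residuals(ContingencyTable(counts)).residuals
        assert np.allclose(np.abs(resid), np.abs(resid[0, 0]), atol=1e-10)


def test_statistics_invariant_under_permutation():
    rng = np.random.default_rng(5)
    counts = rng.integers(1, 50, size=(3, 4))
    base_p = pearson_chi_square(ContingencyTable(counts)).statistic
    base_g = likelihood_ratio_test(ContingencyTable(counts)).statistic
    for _ in range(5):
        perm = counts[rng.permutation(3)][:, rng.permutation(4)]
        assert pearson_chi_square(ContingencyTable(perm)).statistic == pytest.approx(base_p)
        assert likelihood_ratio_test(ContingencyTable(perm)).statistic == pytest.approx(base_g)


def test_g_approaches_pearson_for_large_balanced_tables():
    rng = np.random.default_rng(13)
    rel_diffs = []
    for n in (200, 2000, 20000):
        probs = np.outer([0.5, 0.5], [0.45, 0.55]).ravel()
        probs = probs / probs.sum()
        counts = rng.multinomial(n, probs).reshape(2, 2) + 1
        table = ContingencyTable(counts)
        chi2 = pearson_chi_square(table).statistic
        g = likelihood_ratio_test(table).statistic
        rel_diffs.append(abs(g - chi2) / max(chi2, 1e-9))
    assert rel_diffs[-1] < 0.05


def test_degenerate_margin_raises():
    with pytest.raises(DegenerateTableError):
        pearson_chi_square(ContingencyTable([[0, 0], [5, 5]]))
    with pytest.raises(DegenerateTableError):
        ContingencyTable([[1]])


def test_monte_carlo_type_I_error_is_calibrated():
    """Under simulated independence (3x2 multinomial, n=1000), the chi-square
    test rejects at the nominal 5% within Monte-Carlo slack."""
    rng = np.random.default_rng(314)
    probs = np.outer([0.5, 0.2, 0.3], [0.55, 0.45]).ravel()
    rejections = 0
    n_reps = 1000
    for _ in range(n_reps):
        counts = rng.multinomial(1000, probs).reshape(3, 2)
        if (counts.sum(0) == 0).any() or (counts.sum(1) == 0).any():
            continue
        if pearson_chi_square(ContingencyTable(counts)).p_value < 0.05:
            rejections += 1
    assert 0.03 <= rejections / n_reps <= 0.07


def test_level_by_treatment_builder_matches_published_table():
    control = BandTypeCounts(665, 201, 322, 446)
    stress = BandTypeCounts(789, 113, 425, 308)
    table = level_by_treatment_table(control, stress)
    assert table.counts.tolist() == [[665, 789], [201, 113], [768, 733]]
    assert table.row_labels == ("unmethylated", "hemimethylated", "fully_methylated")
    wide = level_by_treatment_table(control, stress, pool_full=False)
    assert wide.counts.shape == (4, 2)
    assert wide.counts.sum() == table.counts.sum()


def test_identical_conditions_give_zero_statistic():
    counts = BandTypeCounts(100, 50, 30, 20)
    table = level_by_treatment_table(counts, counts)
    assert pearson_chi_square(table).statistic == pytest.approx(0.0, abs=1e-12)


def test_injected_level_shift_is_detected():
    """A hemi-to-full shift of 60 loci out of 1000 per condition rejects
    independence in nearly every replicate."""
    rng = np.random.default_rng(21)
    p_control = np.array([0.5, 0.2, 0.3])
    p_stress = np.array([0.5, 0.14, 0.36])
    rejected = 0
    for _ in range(100):
        control = rng.multinomial(1000, p_control)
        stress = rng.multinomial(1000, p_stress)
        table = ContingencyTable(np.column_stack([control, stress]))
        if pearson_chi_square(table).p_value < 0.05:
            rejected += 1
    assert rejected >= 90
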