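"""RRT aggregation, permutation significance, and downstream summaries."""

import numpy as np
import pandas as pd
import pytest

from riboresidence.genetics import SENSE_CODONS
from riboresidence.rrt_engine import (
    PermutationConfig,
    brute_force_rrt,
    compare_profiles,
    dwell_time_ms,
    gc_group_means,
    permutation_pvalue,
    permutation_pvalues,
    rrt_profile,
    usage_correlation,
    window_frequency,
)
from riboresidence.window_engine import CodonWindow


def mk_window(counts, codon="CTC"):
    return CodonWindow("g", 15, codon, np.array(counts, dtype=np.int64))


def test_window_frequency_examples():
    assert np.allclose(window_frequency([10] * 10).f, 0.1)
    counts = [8, 8, 8, 8, 8, 30, 8, 8, 8, 8]
    assert window_frequency(counts).f[5] == pytest.approx(30 / 102)
    assert window_frequency([20] + [0] * 9).f[0] == 1.0
    with pytest.raises(ValueError, match="zero total"):
        window_frequency([0] * 10)


def test_rrt_profile_uniform_windows_give_one():
    windows = {"CTC": [mk_window([10] * 10) for _ in range(5)]}
    profile = rrt_profile(windows)
    assert np.allclose(profile.rrt.loc["CTC"], 1.0)
    assert profile.n_windows["CTC"] == 5
    assert profile.rrt.loc["AAA"].isna().all()  # missing codons stay NA


def test_rrt_profile_single_peaked_window():
    windows = {"CTC": [mk_window([8, 8, 8, 8, 8, 30, 8, 8, 8, 8])]}
    profile = rrt_profile(windows)
    assert profile.rrt.loc["CTC", 6] == pytest.approx(10 * 30 / 102)


def test_rrt_profile_mean_of_two_windows():
    # position-6 frequencies 0.2 and 0.178 -> mean 0.189 -> RRT 1.89
    w1 = mk_window([16, 16, 16, 16, 16, 20, 0, 0, 0, 0])  # f6 = 0.2
    w2 = mk_window([90, 90, 90, 91, 90, 178, 90, 91, 90, 100])  # f6 = 0.178
    profile = rrt_profile({"CTC": [w1, w2]})
    assert profile.rrt.loc["CTC", 6] == pytest.approx(1.89)


def test_rrt_rows_sum_to_k_with_mean_aggregator(uniform_sim_windows):
    profile = rrt_profile(uniform_sim_windows)
    sums = profile.rrt.sum(axis=1).dropna()
    assert np.allclose(sums, 10.0, atol=1e-10)


def test_engine_matches_brute_force_oracle(uniform_sim_windows):
    profile = rrt_profile(uniform_sim_windows)
    oracle = brute_force_rrt(uniform_sim_windows)
    pd.testing.assert_frame_equal(profile.rrt, oracle, atol=1e-12, rtol=0)


def test_median_aggregator_tracks_mean(uniform_sim_windows):
    by_mean = rrt_profile(uniform_sim_windows, "mean")
    by_median = rrt_profile(uniform_sim_windows, "median")
    assert compare_profiles(by_mean, by_median, position=6) > 0.5


def test_exhaustive_permutation_single_window():
    p = permutation_pvalues(
        [mk_window([20] + [0] * 9)], PermutationConfig(mode="exhaustive-oracle")
    )
    assert p[0] == pytest.approx(0.2)


def test_permutation_p_is_one_for_flat_window():
    p = permutation_pvalues([mk_window([5] * 10)], PermutationConfig(n_perm=500, seed=1))
    assert np.allclose(p, 1.0)


def test_sampled_permutation_agrees_with_exhaustive():
    windows = [
        CodonWindow("g", 9, "AAA", np.array([3, 1, 0, 2], dtype=np.int64)),
        CodonWindow("g", 30, "AAA", np.array([1, 1, 4, 0], dtype=np.int64)),
        CodonWindow("g", 55, "AAA", np.array([0, 5, 2, 1], dtype=np.int64)),
    ]
    exact = permutation_pvalues(windows, PermutationConfig(mode="exhaustive-oracle"))
    n_perm = 4000
    sampled = permutation_pvalues(windows, PermutationConfig(n_perm=n_perm, seed=5))
    se = np.sqrt(exact * (1 - exact) / n_perm)
    assert np.all(np.abs(sampled - exact) <= 3 * (2 * se) + 4 / n_perm)


def test_permutation_is_deterministic_per_seed():
    windows = [mk_window([4, 0, 7, 2, 1, 6, 0, 0, 3, 2]) for _ in range(4)]
    cfg = PermutationConfig(n_perm=300, seed=42)
    assert np.array_equal(permutation_pvalues(windows, cfg), permutation_pvalues(windows, cfg))
    assert permutation_pvalue(windows, 6, cfg) == permutation_pvalues(windows, cfg)[5]


def test_usage_correlation_trivial_cases():
    usage = pd.Series(np.linspace(1, 60, 61), index=list(SENSE_CODONS))
    assert usage_correlation(usage, usage).pearson == pytest.approx(1.0)
    inverted = 2.0 - 0.01 * usage
    res = usage_correlation(inverted, usage)
    assert res.pearson == pytest.approx(-1.0)
    assert res.spearman == pytest.approx(-1.0)


def test_usage_correlation_missing_codon_errors():
    usage = pd.Series(1.0, index=list(SENSE_CODONS))
    rrt = usage.drop("AAA")
    with pytest.raises(ValueError, match="AAA"):
        usage_correlation(rrt, usage)


def test_gc_group_means_flat_profile():
    flat = pd.Series(1.0, index=list(SENSE_CODONS))
    res = gc_group_means(flat)
    assert res.mean_high == res.mean_low == 1.0
    assert res.p_ttest == 1.0


def test_dwell_time_arithmetic():
    assert dwell_time_ms(1.0, 50) == 50.0
    assert dwell_time_ms(1.89, 50) == pytest.approx(94.5)
    with pytest.raises(ValueError):
        dwell_time_ms(-0.1, 50)
    with pytest.raises(ValueError):
        dwell_time_ms(1.0, 0)


def test_compare_profiles_self_and_reversed():
    rng = np.random.default_rng(0)
    vals = pd.Series(rng.normal(1, 0.2, 61), index=list(SENSE_CODONS))
    assert compare_profiles(vals, vals) == pytest.approx(1.0)
    reversed_ranks = pd.Series(vals.max() + vals.min() - vals, index=vals.index)
    assert compare_profiles(vals, reversed_ranks) == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="codon sets"):
        compare_profiles(vals, vals.drop("AAA"))


def test_profile_tsv_round_trip(tmp_path, uniform_sim_windows):
    from riboresidence.rrt_engine import RRTProfile, attach_pvalues

    profile = rrt_profile(uniform_sim_windows)
    attach_pvalues(profile, uniform_sim_windows, PermutationConfig(n_perm=100, seed=2))
    path = tmp_path / "rrt.tsv"
    profile.to_tsv(path)
    loaded = RRTProfile.from_tsv(path)
    pd.testing.assert_frame_equal(
        loaded.rrt, profile.rrt, atol=1e-4, rtol=0,
        check_column_type=False, check_names=False,
    )
    assert loaded.k == profile.k
    assert (loaded.n_windows == profile.n_windows).all()
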