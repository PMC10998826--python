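import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata, wilcoxon

from lutidose import stats_report as sr
from lutidose.phantom_sim import load_clinical_tables


def brute_force_p(diffs) -> float:
    """Independent oracle: enumerate all 2^n sign assignments explicitly."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.sum(ranks[list(signs)]) for signs in
          (np.array(s, dtype=bool) for s in itertools.product([0, 1], repeat=len(d)))]
    ws = np.array(ws)
    p_low = np.mean(ws <= w_obs + 1e-12)
    p_high = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_low, p_high))


class TestExactWilcoxon:
    def test_all_increases_n6(self):
        # six positive differences: p = 2/64 exactly
        res = sr.wilcoxon_signed_rank_exact([1, 2, 3, 4, 5, 6],
                                            [2, 3, 4, 5, 6, 7])
        assert res.p_two_sided == pytest.approx(2 / 64)
        assert res.W_plus == 21 and res.W_minus == 0

    def test_rank_sum_identity_without_ties(self):
        rng = np.random.default_rng(5)
        wo = rng.normal(10, 2, 9)
        w = wo + rng.normal(0, 1, 9)
        res = sr.wilcoxon_signed_rank_exact(wo, w)
        n = res.n_effective
        assert res.W_plus + res.W_minus == n * (n + 1) / 2

    @pytest.mark.parametrize("n", range(1, 11))
    def test_matches_brute_force_enumeration_tie_free(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            d = rng.normal(0, 1, n)
            d = np.where(d == 0, 0.1, d)
            res = sr.wilcoxon_signed_rank_exact(np.zeros(n), d)
            assert res.p_two_sided == pytest.approx(brute_force_p(d), abs=1e-12)

    def test_matches_brute_force_with_ties(self):
        d = np.array([1.0, -1.0, 2.0, 2.0, -3.0, 4.0])
        res = sr.wilcoxon_signed_rank_exact(np.zeros(6), d)
        assert res.p_two_sided == pytest.approx(brute_force_p(d), abs=1e-12)

    def test_matches_scipy_exact_tie_free(self):
        rng = np.random.default_rng(7)
        wo = rng.normal(50, 5, 10)
        w = wo + rng.normal(1, 2, 10)
        ours = sr.wilcoxon_signed_rank_exact(wo, w)
        ref = wilcoxon(w, wo, method="exact", alternative="two-sided")
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-10)

    @given(st.lists(st.sampled_from([-3.0, -1.5, 1.0, 2.5, 4.0]),
                    min_size=2, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_zero_difference_pairs_never_change_p(self, diffs):
        d = np.array(diffs)
        base = sr.wilcoxon_signed_rank_exact(np.zeros_like(d), d)
        padded = np.concatenate([d, [0.0, 0.0]])
        with_zeros = sr.wilcoxon_signed_rank_exact(np.zeros_like(padded), padded)
        assert with_zeros.p_two_sided == pytest.approx(base.p_two_sided)
        assert with_zeros.n_effective == base.n_effective

    def test_all_zero_degenerate(self):
        res = sr.wilcoxon_signed_rank_exact([1.0, 2.0], [1.0, 2.0])
        assert res.p_two_sided == 1.0 and res.method == "degenerate"

    def test_large_n_normal_approximation_flagged(self):
        rng = np.random.default_rng(3)
        wo = rng.normal(0, 1, 30)
        w = wo + rng.normal(0.5, 1, 30)
        res = sr.wilcoxon_signed_rank_exact(wo, w)
        assert res.method == "normal_approx"
        ref = wilcoxon(w, wo, correction=True, alternative="two-sided",
                       method="approx")
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=0.05)


@pytest.fixture(scope="module")
def paired():
    _, doses = load_clinical_tables()
    return sr.assemble_paired_tables(doses)


@pytest.fixture(scope="module")
def report():
    return sr.build_report("fixtures")


class TestClinicalEndpoints:
    @pytest.mark.parametrize("endpoint, expected_p", [
        ("tumor_dose", 2 / 64),      # 6 increases -> 0.03
        ("kidney_dose", 2 / 256),    # 8 increases -> 0.01
        ("stomach_dose", 2 / 256),   # 8 increases -> 0.01
        ("ratio_kidney", 14 / 64),   # W+ = 4 of 21 -> 0.22
        ("ratio_stomach", 6 / 32),   # one zero dropped, n = 5 -> 0.19
        ("ratio_marrow", 28 / 64),   # min tail = 6 -> 0.44
    ])
    def test_published_p_values(self, paired, endpoint, expected_p):
        s = sr.summarize_endpoint(paired[endpoint])
        assert s["test"].p_two_sided == pytest.approx(expected_p, abs=1e-12)

    def test_ratio_kidney_wplus(self, paired):
        res = sr.summarize_endpoint(paired["ratio_kidney"])["test"]
        assert res.W_plus == 4.0 and res.n_effective == 6

    def test_marrow_dose_p_does_not_reproduce_printed(self, paired):
        # printed 0.01; printed two-decimal values give 6 positive diffs after
        # dropping two zeros -> 2/64 ~ 0.03 (flagged, not forced)
        s = sr.summarize_endpoint(paired["marrow_dose"])
        assert s["test"].n_effective == 6
        assert s["test"].p_two_sided == pytest.approx(2 / 64)

    def test_tumor_medians_and_fold(self, paired):
        s = sr.summarize_endpoint(paired["tumor_dose"])
        assert s["median_without"] == pytest.approx(0.275)
        assert s["median_with"] == pytest.approx(0.74)
        assert round(s["fold_of_rounded_medians"], 1) == 2.6

    def test_identical_arms(self):
        df = pd.DataFrame({"unit_id": ["a", "b", "c"],
                           "value_without": [1.0, 2.0, 3.0],
                           "value_with": [1.0, 2.0, 3.0]})
        s = sr.summarize_endpoint(df)
        assert s["fold"] == 1.0 and s["test"].p_two_sided == 1.0

    def test_empty_endpoint_errors(self):
        with pytest.raises(ValueError):
            sr.summarize_endpoint(pd.DataFrame(columns=["value_without", "value_with"]))

    def test_medians_match_sort_oracle(self, paired):
        for ep, pairs in paired.items():
            for col in ("value_without", "value_with"):
                v = sorted(pairs[col])
                n = len(v)
                oracle = v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2])
                got = sr.summarize_endpoint(pairs)[f"median_{col.split('_')[1]}"]
                assert got == pytest.approx(oracle)


class TestBuildReport:
    def test_marrow_ratio_with_median(self, report):
        row = report["dose_summary"].set_index("endpoint").loc["ratio_marrow"]
        assert row["median_with"] == pytest.approx(19.05)
        assert row["printed_median_with"] == 19.1
        assert row["median_match"]

    def test_flags_known_mismatches_without_forcing(self, report):
        ds = report["dose_summary"].set_index("endpoint")
        assert not ds.loc["marrow_dose", "median_match"]   # 0.04 vs printed 0.05
        assert not ds.loc["marrow_dose", "p_match"]        # 0.03 vs printed 0.01
        ss = report["stability_summary"].set_index("time_min")
        assert ss.loc[60, "median_match"]
        assert not ss.loc[15, "median_match"]  # typeset-ambiguous cells flagged

    def test_ratio_consistency_all_within_rounding(self, report):
        rc = report["ratio_consistency"]
        assert len(rc) == 36  # 6 lesions x 2 arms x 3 organs
        assert rc["consistent"].all()

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            sr.build_report("fixtures", tables=(pd.DataFrame(), pd.DataFrame()))
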