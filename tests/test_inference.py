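"""Statistical engine: rm-ANOVA vs sums-of-squares oracle, t, FDR, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from crossmodal_eeg.inference import (
    apply_fdr,
    bh_fdr,
    paired_t,
    rm_anova,
    rm_anova_power,
    simple_effects,
)

FACTORS = ["A", "B", "D"]  # statsmodels reserves the name 'C'


def long_table(Y):
    """Y: subjects x 2 x 2 x 2 cell array -> long-format within-subject table."""
    rows = []
    n = Y.shape[0]
    for s in range(n):
        for a in range(2):
            for b in range(2):
                for c in range(2):
                    rows.append(
                        {"participant": s, "A": f"a{a}", "B": f"b{b}",
                         "D": f"c{c}", "value": Y[s, a, b, c]}
                    )
    return pd.DataFrame(rows)


def anova_contrast_oracle(Y):
    """Independent F statistics for a 2x2x2 within design via subject contrasts.

    For two-level factors each term's F equals the squared one-sample t of
    the per-subject contrast score (difference of cell-mean averages), an
    algebraic identity of the sums-of-squares decomposition.
    """
    n = Y.shape[0]
    signs = {0: np.array([1.0, 1.0]), 1: np.array([1.0, -1.0])}
    out = {}
    terms = [
        ("A", (1, 0, 0)), ("B", (0, 1, 0)), ("D", (0, 0, 1)),
        ("A x B", (1, 1, 0)), ("A x D", (1, 0, 1)), ("B x D", (0, 1, 1)),
        ("A x B x D", (1, 1, 1)),
    ]
    for name, (ia, ib, ic) in terms:
        w = np.einsum(
            "a,b,c->abc", signs[ia] / 2, signs[ib] / 2, signs[ic] / 2
        )
        scores = np.einsum("sabc,abc->s", Y, w)
        t = scores.mean() / (scores.std(ddof=1) / np.sqrt(n))
        out[name] = t**2
    return out


class TestRmAnova:
    def test_full_factorial_matches_contrast_oracle(self):
        rng = np.random.default_rng(21)
        Y = rng.standard_normal((8, 2, 2, 2))
        res = rm_anova(long_table(Y), within=FACTORS)
        oracle = anova_contrast_oracle(Y)
        assert len(res) == 7
        for r in res:
            assert r.statistic == pytest.approx(oracle[r.effect], abs=1e-9)
            df1, df2 = r.df
            assert (df1, df2) == (1.0, 7.0)
            p_oracle = sps.f.sf(oracle[r.effect], 1, 7)
            assert r.p == pytest.approx(p_oracle, abs=1e-9)

    def test_single_factor_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(22)
        x = rng.standard_normal(10)
        y = rng.standard_normal(10) + 0.5
        tbl = pd.DataFrame(
            {
                "participant": list(range(10)) * 2,
                "A": ["a0"] * 10 + ["a1"] * 10,
                "value": np.concatenate([x, y]),
            }
        )
        res = rm_anova(tbl, within=["A"])
        t = paired_t(x, y)
        assert res[0].statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert res[0].p == pytest.approx(t.p, rel=1e-9)

    def test_constant_data_yields_zero_f(self):
        Y = np.full((6, 2, 2, 2), 3.14)
        res = rm_anova(long_table(Y), within=FACTORS)
        for r in res:
            assert r.statistic == 0.0
            assert r.p == 1.0

    def test_invariant_to_per_participant_offsets(self):
        rng = np.random.default_rng(23)
        Y = rng.standard_normal((8, 2, 2, 2))
        shifted = Y + rng.normal(0, 10, size=(8, 1, 1, 1))
        res_a = rm_anova(long_table(Y), within=FACTORS)
        res_b = rm_anova(long_table(shifted), within=FACTORS)
        for ra, rb in zip(res_a, res_b):
            assert ra.statistic == pytest.approx(rb.statistic, rel=1e-8)

    def test_incomplete_crossing_rejected(self):
        tbl = long_table(np.zeros((4, 2, 2, 2))).iloc[:-1]
        with pytest.raises(ValueError, match="missing|incomplete"):
            rm_anova(tbl, within=FACTORS)

    def test_eta_p2_matches_ss_ratio(self):
        """eta_p^2 from F equals SS_effect / (SS_effect + SS_error)."""
        rng = np.random.default_rng(24)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12) + 1.0
        d = (y - x) / 2
        ss_effect = 2 * 12 * d.mean() ** 2
        ss_error = 2 * ((d - d.mean()) ** 2).sum()
        tbl = pd.DataFrame(
            {
                "participant": list(range(12)) * 2,
                "A": ["a0"] * 12 + ["a1"] * 12,
                "value": np.concatenate([x, y]),
            }
        )
        res = rm_anova(tbl, within=["A"])
        assert res[0].effect_size == pytest.approx(
            ss_effect / (ss_effect + ss_error), rel=1e-9
        )

    def test_greenhouse_geisser_applied_beyond_two_levels(self):
        rng = np.random.default_rng(25)
        base = rng.standard_normal((12, 4))
        base[:, 3] += 2.0 * base[:, 0]  # break sphericity
        rows = [
            {"participant": s, "A": f"a{k}", "value": base[s, k]}
            for s in range(12)
            for k in range(4)
        ]
        res = rm_anova(pd.DataFrame(rows), within=["A"])
        uncorrected = sps.f.sf(res[0].statistic, 3, 33)
        assert res[0].p >= uncorrected  # GG correction cannot sharpen p


class TestSimpleEffects:
    def test_recovers_stratified_injection(self):
        rng = np.random.default_rng(26)
        n = 12
        rows = []
        for s in range(n):
            for stim in ("left", "right"):
                for att in ("left", "right"):
                    val = rng.normal(0, 0.1)
                    if stim == "left" and att == "left":
                        val -= 2.0
                    rows.append(
                        {"participant": s, "stimulus": stim, "attention": att,
                         "value": val}
                    )
        tbl = pd.DataFrame(rows)
        left = simple_effects(tbl, compare="attention", at={"stimulus": "left"})
        right = simple_effects(tbl, compare="attention", at={"stimulus": "right"})
        assert left.p < 0.001
        assert right.p > 0.05

    def test_equals_paired_t_within_stratum(self):
        rng = np.random.default_rng(27)
        n = 9
        tbl = pd.DataFrame(
            {
                "participant": list(range(n)) * 2,
                "attention": ["att"] * n + ["unatt"] * n,
                "stimulus": "left",
                "value": rng.standard_normal(2 * n),
            }
        )
        res = simple_effects(tbl, compare="attention", at={"stimulus": "left"})
        x = tbl[tbl["attention"] == "att"]["value"].to_numpy()
        y = tbl[tbl["attention"] == "unatt"]["value"].to_numpy()
        ref = paired_t(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)


class TestPairedT:
    def test_identical_vectors(self):
        x = np.arange(5.0)
        res = paired_t(x, x)
        assert (res.statistic, res.p, res.effect_size) == (0.0, 1.0, 0.0)

    def test_constant_nonzero_difference_is_deterministically_infinite(self):
        res = paired_t(np.array([2.0, 3.0, 4.0]), np.array([1.0, 2.0, 3.0]))
        assert res.statistic == np.inf and res.p == 0.0

    def test_direction_with_near_constant_difference(self):
        rng = np.random.default_rng(28)
        y = rng.standard_normal(8)
        x = y + 1.0 + rng.normal(0, 1e-3, 8)
        res = paired_t(x, y)
        assert res.effect_size > 10
        assert res.statistic > 0

    def test_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.0, 4.0, 4.0, 7.0])
        d = x - y
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_expected = 2 * sps.t.sf(abs(t_expected), 4)
        res = paired_t(x, y)
        assert res.statistic == pytest.approx(t_expected, rel=1e-12)
        assert res.p == pytest.approx(p_expected, rel=1e-12)
        assert res.df == 4


class TestFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_stepup_hand_case(self):
        """p = {0.01..0.05}: p(i)*5/i then cumulative min from the top -> all 0.05."""
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(adj, 0.05)

    def test_identical_ps_unchanged(self):
        adj = bh_fdr([0.2, 0.2, 0.2])
        assert np.allclose(adj, 0.2)

    def test_empty_family(self):
        assert bh_fdr([]).size == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_never_decreases_and_order_invariant(self, ps):
        ps = np.asarray(ps)
        adj = bh_fdr(ps)
        assert np.all(adj >= ps - 1e-15)
        assert np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(ps))
        adj_perm = bh_fdr(ps[perm])
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        assert np.allclose(adj_perm[inv], adj)


class TestPower:
    def test_huge_effect_saturates_at_minimum_n(self):
        assert rm_anova_power(f=50.0, power=0.5) == 2

    def test_monotone_in_effect_and_target(self):
        n_small_f = rm_anova_power(f=0.25)
        n_large_f = rm_anova_power(f=0.50)
        assert n_large_f <= n_small_f
        n_lo = rm_anova_power(f=0.40, power=0.80)
        n_hi = rm_anova_power(f=0.40, power=0.95)
        assert n_hi >= n_lo

    def test_unattainable_power_raises(self):
        with pytest.raises(ValueError, match="not attainable"):
            rm_anova_power(f=0.01, power=0.999, n_max=20)


def test_apply_fdr_sets_monotone_adjusted_values():
    rng = np.random.default_rng(29)
    x = rng.standard_normal((6, 5))
    results = [paired_t(x[:, i], x[:, (i + 1) % 5]) for i in range(5)]
    apply_fdr(results)
    for r in results:
        assert r.p_fdr >= r.p - 1e-15


def test_type_one_error_rate_controlled_on_null_tables():
    """Paired-t rejection rate at alpha=.05 stays within binomial bounds."""
    rng = np.random.default_rng(30)
    n_rep, n = 500, 25
    rejections = 0
    for _ in range(n_rep):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        if paired_t(x, y).p < 0.05:
            rejections += 1
    lo, hi = sps.binom.ppf([0.005, 0.995], n_rep, 0.05)
    assert lo <= rejections <= hi
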