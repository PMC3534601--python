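"""Rank-sum and t screening statistics: oracles, symmetry, calibration."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from xbias.errors import DegenerateInputError, InsufficientDataError, MetadataError
from xbias.model import ExpressionMatrix, SampleTable
from xbias.stats import (
    fold_change,
    rank_sum_p,
    rank_sum_p_matrix,
    recall_at,
    t_test_p,
    t_test_p_matrix,
)
from xbias.stats import test_tissue as screen_tissue

groups = st.lists(st.integers(0, 30), min_size=2, max_size=8)


class TestRankSum:
    def test_identical_multisets_give_p_near_one(self):
        assert rank_sum_p([1, 2, 3, 4], [4, 3, 2, 1]) >= 0.99

    def test_matches_exact_enumeration_on_separated_triples(self):
        """{1,2,3} vs {4,5,6}: exact two-sided p over all C(6,3)=20 rank
        assignments is 2/20 = 0.10; the approximation must land within 0.05."""
        p = rank_sum_p([1, 2, 3], [4, 5, 6])
        assert abs(p - 0.10) <= 0.05

    @given(groups, groups)
    def test_swap_symmetry(self, xs, ys):
        assert rank_sum_p(xs, ys) == pytest.approx(rank_sum_p(ys, xs), abs=1e-12)

    @given(groups, groups)
    def test_agrees_with_reference_asymptotic_implementation(self, xs, ys):
        """Tie-corrected continuity-corrected normal approximation equals the
        standard library implementation of the same approximation."""
        mine = rank_sum_p(xs, ys)
        ref = sps.mannwhitneyu(
            xs, ys, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        assert mine == pytest.approx(float(ref), abs=1e-10)

    def test_all_tied_rows_give_p_one(self):
        p = rank_sum_p_matrix(np.ones((2, 3)), np.ones((2, 4)))
        np.testing.assert_allclose(p, 1.0)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            rank_sum_p([1.0], [2.0, 3.0])


class TestTTest:
    def test_type_i_error_calibrated(self):
        """Equal-mean Gaussian groups, n=50 each: rejection rate at 0.05 over
        1000 replicates must sit in [0.03, 0.07]."""
        rng = np.random.default_rng(2024)
        xs = rng.normal(0, 1, size=(1000, 50))
        ys = rng.normal(0, 1, size=(1000, 50))
        p = t_test_p_matrix(xs, ys)
        rate = float((p < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_complete_separation_with_jitter(self):
        rng = np.random.default_rng(0)
        xs = rng.normal(0, 1e-9, 4)
        ys = 1.0 + rng.normal(0, 1e-9, 4)
        assert t_test_p(xs, ys) < 1e-6

    @given(groups, groups)
    def test_swap_symmetry(self, xs, ys):
        try:
            assert t_test_p(xs, ys) == pytest.approx(t_test_p(ys, xs), abs=1e-12)
        except DegenerateInputError:
            pass

    def test_zero_variance_conventions(self):
        assert t_test_p([1.0, 1.0], [1.0, 1.0]) == 1.0
        with pytest.raises(DegenerateInputError):
            t_test_p([0.0, 0.0], [1.0, 1.0])


class TestFoldChange:
    def test_equal_means(self):
        delta, fc = fold_change([2.0, 4.0], [3.0, 3.0])
        assert delta == 0.0 and fc == 1.0

    def test_seven_log2_units_is_128_fold(self):
        delta, fc = fold_change([10.0, 10.0], [3.0, 3.0])
        assert delta == 7.0 and fc == 128.0

    @given(
        st.lists(st.floats(-8, 8), min_size=1, max_size=6),
        st.lists(st.floats(-8, 8), min_size=1, max_size=6),
    )
    def test_swap_inverts_fold_change(self, xs, ys):
        _, fc = fold_change(xs, ys)
        _, fc_swapped = fold_change(ys, xs)
        assert fc * fc_swapped == pytest.approx(1.0, rel=1e-9)

    def test_empty_group(self):
        with pytest.raises(InsufficientDataError):
            fold_change([], [1.0])


class TestWilcoxonSize:
    """Exact attainable size of the approximate screen at the study's
    relaxed design (20 samples per sex)."""

    @staticmethod
    def _u_pmf(m: int, n: int) -> np.ndarray:
        """Exact null pmf of the Mann-Whitney U statistic (no ties)."""
        import sys
        from functools import lru_cache

        sys.setrecursionlimit(100_000)

        @lru_cache(maxsize=None)
        def count(mm, nn, u):
            if u < 0:
                return 0
            if mm == 0 or nn == 0:
                return 1 if u == 0 else 0
            return count(mm - 1, nn, u - nn) + count(mm, nn - 1, u)

        pmf = np.array([count(m, n, u) for u in range(m * n + 1)], dtype=float)
        return pmf / pmf.sum()

    def test_screen_is_conservative_and_calibrated_at_its_exact_size(self):
        """The continuity-corrected normal approximation at 20 vs 20 has an
        exact size of ~0.0006 at nominal 0.001 — conservative, never
        anticonservative — and a 20,000-probe null screen produces a count
        inside the 99% binomial interval around that exact size."""
        m = n = 20
        pmf = self._u_pmf(m, n)
        us = np.arange(m * n + 1)
        mu = m * n / 2
        sigma = np.sqrt(m * n * (m + n + 1) / 12)
        z = (us - mu - 0.5 * np.sign(us - mu)) / sigma
        p = 2 * sps.norm.sf(np.abs(z))
        exact_size = float(pmf[p < 0.001].sum())
        assert 0.0003 <= exact_size <= 0.001

        from xbias.simulate import SimConfig, TissueEffects, generate_null

        cfg = SimConfig(
            seed=1, samples_per_sex=20, n_probes_a=18572, n_probes_x=1428,
            n_probes_y=0, n_probes_na=0, tissues=(TissueEffects("t0"),),
            clusters=(), n_escapees=0, xist_like=False,
        )
        exp = generate_null(cfg)
        res = screen_tissue(exp.matrices["t0"], exp.samples.for_tissue("t0"), 0.001)
        called = int((res["call"] != "ns").sum())
        n_probes = len(res)
        lo = sps.binom.ppf(0.005, n_probes, exact_size)
        hi = sps.binom.ppf(0.995, n_probes, exact_size)
        assert lo <= called <= hi


def _tissue_data(seed=5, n_probes=300, n_per=20, planted=None):
    rng = np.random.default_rng(seed)
    probes = [f"p{i}" for i in range(n_probes)]
    f_ids = [f"F{i}" for i in range(n_per)]
    m_ids = [f"M{i}" for i in range(n_per)]
    delta = np.zeros(n_probes)
    for idx, d in (planted or {}).items():
        delta[idx] = d
    vals = np.concatenate(
        [
            rng.normal(8 + delta[:, None] / 2, 0.5, size=(n_probes, n_per)),
            rng.normal(8 - delta[:, None] / 2, 0.5, size=(n_probes, n_per)),
        ],
        axis=1,
    )
    m = ExpressionMatrix(
        pd.DataFrame(vals, index=pd.Index(probes, name="probe_id"), columns=f_ids + m_ids)
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": f_ids + m_ids,
                "sex": ["female"] * n_per + ["male"] * n_per,
                "tissue": ["kidney"] * (2 * n_per),
            }
        )
    )
    return m, samples


class TestTestTissue:
    def test_planted_effect_called_female(self):
        m, samples = _tissue_data(planted={0: 1.0, 1: -1.0})
        res = screen_tissue(m, samples, alpha=0.001)
        assert res.iloc[0]["call"] == "female"
        assert res.iloc[1]["call"] == "male"
        assert res.iloc[0]["fold_change"] == pytest.approx(2.0, rel=0.35)

    def test_alpha_zero_calls_everything_ns(self):
        m, samples = _tissue_data(planted={0: 2.0})
        res = screen_tissue(m, samples, alpha=0.0)
        assert (res["call"] == "ns").all()

    def test_label_swap_antisymmetry(self):
        """Swapping sex labels flips every call, inverts fold-changes, and
        leaves the p-values untouched."""
        m, samples = _tissue_data(planted={0: 1.0, 5: -0.8})
        res = screen_tissue(m, samples, alpha=0.001)
        flipped_df = samples.df.assign(
            sex=samples.df["sex"].map({"female": "male", "male": "female"})
        )
        res_swapped = screen_tissue(m, SampleTable(flipped_df), alpha=0.001)
        np.testing.assert_allclose(res["p_wilcoxon"], res_swapped["p_wilcoxon"])
        np.testing.assert_allclose(
            res["fold_change"] * res_swapped["fold_change"], 1.0, rtol=1e-9
        )
        swap = {"female": "male", "male": "female", "ns": "ns"}
        assert (res["call"].map(swap) == res_swapped["call"]).all()

    def test_threshold_monotonicity(self):
        """The biased set at alpha=0.001 is a subset of the set at 0.01."""
        m, samples = _tissue_data(planted={i: 0.5 for i in range(30)})
        res = screen_tissue(m, samples, alpha=0.001)
        strict = set(res.index[recall_at(res, 0.001) != "ns"])
        relaxed = set(res.index[recall_at(res, 0.01) != "ns"])
        assert strict <= relaxed
        assert len(relaxed) > 0

    def test_missing_sex_annotation_is_metadata_error(self):
        m, samples = _tissue_data()
        broken = SampleTable(samples.df.iloc[:-1])
        with pytest.raises(MetadataError):
            screen_tissue(m, broken)

    def test_monte_carlo_power_matches_normal_theory(self):
        """Planted delta=1, n=20/sex, sd=0.5: the recovery rate at p<0.001
        over replicates must agree with the normal-theory approximation
        (Wilcoxon ARE 3/pi relative to the t-test) and exceed 90%."""
        n_planted, n_reps = 100, 50
        hits = 0
        for rep in range(n_reps):
            m, samples = _tissue_data(
                seed=1000 + rep,
                n_probes=n_planted,
                n_per=20,
                planted={i: 1.0 for i in range(n_planted)},
            )
            res = screen_tissue(m, samples, alpha=0.001)
            hits += int((res["call"] == "female").sum())
        rate = hits / (n_planted * n_reps)
        z_eff = 1.0 / (0.5 * np.sqrt(2 / 20)) * np.sqrt(3 / np.pi)
        theory = float(sps.norm.sf(sps.norm.isf(0.0005) - z_eff))
        assert rate >= 0.90
        assert rate == pytest.approx(theory, abs=0.05)
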