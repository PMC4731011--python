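"""Normalisation, filtering, smoothing and replicate-consistency checks."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pecapipe.containers import ExpressionMatrix
from pecapipe.preprocess import (
    complete_case_filter,
    lfq_sum_normalize,
    log_transform,
    lowess_smooth,
    quantile_normalize,
    rcm,
    trv_filter,
    trv_spikiness,
)

GRID = [0, 0.5, 1, 2, 8, 16, 24, 30]


def _em(values, level="rna", scale="natural", columns=None, rep=1):
    df = pd.DataFrame(
        values,
        index=[f"G{i:06d}" for i in range(1, len(values) + 1)],
        columns=columns if columns is not None else GRID[: len(values[0])],
    )
    return ExpressionMatrix(df, level=level, scale=scale, replicate=rep)


class TestLogTransform:
    def test_values(self):
        m = _em([[np.e, 1.0, 4.0]], columns=[0, 1, 2])
        out = log_transform(m)
        assert out.scale == "log"
        assert out.values.iloc[0, 0] == pytest.approx(1.0)
        assert out.values.iloc[0, 1] == pytest.approx(0.0)

    def test_zero_raises_naming_gene_and_time(self):
        m = _em([[1.0, 0.0, 2.0]], columns=[0, 1, 2])
        with pytest.raises(ValueError, match="G000001.*1"):
            log_transform(m)


class TestQuantileNormalize:
    def test_hand_example(self):
        """Columns [2,5,3] and [4,2,9]: reference {2, 3.5, 7}."""
        df = pd.DataFrame({0.0: [2.0, 5.0, 3.0], 1.0: [4.0, 2.0, 9.0]},
                          index=["a", "b", "c"])
        m = ExpressionMatrix(df, level="rna", scale="log")
        out = quantile_normalize(m).values
        assert list(out[0.0]) == [2.0, 7.0, 3.5]
        assert list(out[1.0]) == [3.5, 2.0, 7.0]

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({0.0: [1.0, 2.0, 3.0], 1.0: [1.0, 2.0, 3.0]})
        m = ExpressionMatrix(df, level="rna", scale="log")
        out = quantile_normalize(m).values
        pd.testing.assert_frame_equal(out, df)

    def test_columns_share_sorted_values(self):
        rng = np.random.default_rng(0)
        m = _em(rng.normal(size=(50, 8)), scale="log")
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 8):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = _em(rng.normal(size=(30, 8)), scale="log")
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        assert np.allclose(once.values, twice.values)

    def test_tie_handling_shares_rank_mean(self):
        df = pd.DataFrame({0.0: [1.0, 1.0, 5.0], 1.0: [10.0, 20.0, 30.0]})
        m = ExpressionMatrix(df, level="rna", scale="log")
        out = quantile_normalize(m).values
        # tie group occupies ranks 1-2; both get the mean reference there
        assert out[0.0].iloc[0] == out[0.0].iloc[1]

    def test_all_missing_column_raises(self):
        df = pd.DataFrame({0.0: [np.nan, np.nan], 1.0: [1.0, 2.0]})
        m = ExpressionMatrix(df, level="rna", scale="log")
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize(m)


class TestLfqSumNormalize:
    def test_hand_example(self):
        """Column [10,20,30,940]: exclude ceil(0.05*4)=1 value, normaliser 60."""
        m = _em([[10.0], [20.0], [30.0], [940.0]], level="protein", columns=[0])
        out = lfq_sum_normalize(m).values[0]
        assert list(out) == pytest.approx([1 / 6, 1 / 3, 1 / 2, 47 / 3])

    def test_all_equal_column(self):
        n = 40
        m = _em([[5.0]] * n, level="protein", columns=[0])
        out = lfq_sum_normalize(m).values[0]
        expected = 1.0 / (n - int(np.ceil(0.05 * n)))
        assert np.allclose(out, expected)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(3, 1, size=(30, 2))
        a = lfq_sum_normalize(_em(vals, level="protein", columns=[0, 1]))
        b = lfq_sum_normalize(_em(vals * np.array([2.0, 7.0]), level="protein", columns=[0, 1]))
        assert np.allclose(a.values, b.values)


class TestCompleteCase:
    def test_intersection_logic(self):
        full = _em(np.ones((3, 8)))
        holed = _em(np.ones((3, 8)), rep=2)
        holed.values.iloc[1, 4] = np.nan
        genes = complete_case_filter([full, holed])
        assert genes == ["G000001", "G000003"]

    def test_gene_absent_from_one_matrix_excluded(self):
        a = _em(np.ones((3, 8)))
        b = _em(np.ones((2, 8)), rep=2)
        assert complete_case_filter([a, b]) == ["G000001", "G000002"]

    def test_empty_result_warns(self):
        a = _em(np.full((2, 8), np.nan))
        with pytest.warns(UserWarning):
            assert complete_case_filter([a]) == []


class TestTrvSpikiness:
    def test_spiky_series_scores_nine(self):
        spk, trv = trv_spikiness([1.0, 2.0, 1.5, 10.0, 1.2, 1.8, 1.4, 1.6])
        assert sorted(trv) == pytest.approx([1.0] + [8.8] + [9.0] * 6)
        assert spk == pytest.approx(9.0)

    def test_smooth_series_scores_near_one(self):
        spk, _ = trv_spikiness([1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7])
        assert spk == pytest.approx(7 / 6, abs=1e-9)

    def test_constant_series_convention(self):
        spk, _ = trv_spikiness([2.0] * 8)
        assert spk == 1.0

    def test_flat_with_one_spike_is_infinite(self):
        spk, _ = trv_spikiness([1.0, 1.0, 1.0, 5.0, 1.0, 1.0, 1.0, 1.0])
        assert np.isinf(spk)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            trv_spikiness([1.0, 2.0])

    @given(
        shift=st.floats(-100, 100),
        scale=st.floats(0.1, 50),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, shift, scale, seed):
        y = np.random.default_rng(seed).normal(size=8)
        s1, _ = trv_spikiness(y)
        s2, _ = trv_spikiness(y * scale + shift)
        assert s1 == pytest.approx(s2, rel=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_large_spike_always_detected(self, seed):
        """A single spike >= 5x the spike-free range pushes spikiness above 3."""
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 0.1, 8)
        spike_free_range = np.ptp(y)
        y[rng.integers(0, 8)] += 5.0 * spike_free_range
        spk, _ = trv_spikiness(y)
        assert spk > 3.0


class TestTrvFilter:
    def test_threshold_separates_fixture_series(self):
        m = _em(
            [[1.0, 2.0, 1.5, 10.0, 1.2, 1.8, 1.4, 1.6],
             [1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7]],
            scale="log",
        )
        kept, report = trv_filter(m, threshold=3.0)
        assert list(kept.gene_ids) == ["G000002"]
        assert not report.loc["G000001", "retained"]
        assert report.loc["G000001", "spikiness"] == pytest.approx(9.0)

    def test_infinite_threshold_keeps_all(self):
        m = _em(np.random.default_rng(0).normal(size=(5, 8)), scale="log")
        kept, _ = trv_filter(m, threshold=np.inf)
        assert kept.n_genes == 5


class TestLowess:
    def test_linear_series_reproduced(self, grid):
        y = 0.3 * grid + 1.0
        out = lowess_smooth(y, grid)
        assert np.allclose(out, y, atol=1e-6)

    def test_constant_series_unchanged(self, grid):
        out = lowess_smooth(np.full(8, 2.5), grid)
        assert np.allclose(out, 2.5)

    def test_zigzag_range_shrinks(self, grid):
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1.0])
        out = lowess_smooth(y, grid)
        assert np.ptp(out) < np.ptp(y)

    def test_matches_reference_r_implementation(self, grid):
        """Cross-check against the R stats::lowess reference at default settings."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the reference smoother")
        y = np.array([0.2, 1.1, 0.4, 1.3, 0.1, 0.9, 0.3, 1.2])
        ours = lowess_smooth(y, grid)
        script = (
            "x<-c(0,0.5,1,2,8,16,24,30);"
            "y<-c(0.2,1.1,0.4,1.3,0.1,0.9,0.3,1.2);"
            "cat(lowess(x,y)$y)"
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        ref = np.array([float(v) for v in res.stdout.split()])
        assert np.allclose(ours, ref, atol=1e-6)


class TestRcm:
    def test_identical_series(self):
        r, p = rcm([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert r == pytest.approx(1.0)

    def test_negated_series(self):
        r, _ = rcm([1, 2, 3, 4.0], [-1, -2, -3, -4.0])
        assert r == pytest.approx(-1.0)

    def test_r_07_at_n8_gives_p_005(self):
        """With 8 time points, r = 0.7 sits exactly at the p ~ 0.05 boundary."""
        x = np.arange(8.0)
        xs = (x - x.mean()) / np.linalg.norm(x - x.mean())
        z = np.random.default_rng(0).normal(size=8)
        z -= z.mean()
        z -= (z @ xs) * xs  # orthogonal to x, still centred
        zs = z / np.linalg.norm(z)
        y = 0.7 * xs + np.sqrt(1 - 0.49) * zs
        r, p = rcm(x, y)
        assert r == pytest.approx(0.7, abs=1e-12)
        assert round(p, 2) == 0.05

    def test_constant_series_sentinel(self):
        r, p = rcm([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4.0])
        assert np.isnan(r) and np.isnan(p)

    def test_p_value_matches_permutation_null(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r_obs, p = rcm(x, y)
        perm = [abs(np.corrcoef(x, rng.permutation(y))[0, 1]) for _ in range(4000)]
        p_perm = np.mean(np.array(perm) >= abs(r_obs))
        assert p == pytest.approx(p_perm, abs=0.05)
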