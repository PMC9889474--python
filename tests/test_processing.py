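"""ICC reliability filter, per-day delta features, table assembly."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltarad.processing import (
    assemble_feature_table,
    base_name,
    compute_icc,
    delta_per_day,
    icc_by_feature,
    retest_filter,
)

finite = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


class TestICC:
    def test_identical_measurements(self):
        a = np.array([1.0, 2.0, 5.0, 9.0, 3.0])
        assert compute_icc(a, a) == 1.0

    def test_zero_variance_convention(self):
        a = np.full(5, 3.0)
        assert compute_icc(a, a) == 1.0

    def test_independent_noise_low_icc(self):
        rng = np.random.default_rng(0)
        low = sum(
            abs(compute_icc(rng.normal(size=30), rng.normal(size=30))) < 0.4
            for _ in range(1000)
        )
        assert low >= 950

    def test_constant_offset_penalized(self):
        # absolute agreement: a large systematic shift destroys reliability.
        # closed form on a 5-point example: ICC(A,1) = (MSR-MSE)/(MSR+MSE+2/n(MSC-MSE))
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a + 10.0
        n, k = 5, 2
        msr, mse = 2 * np.var(a, ddof=1), 0.0
        msc = n * 2 * (5.0) ** 2 / (k - 1)  # column means differ by 10 -> (+-5)^2
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert compute_icc(a, b) == pytest.approx(expected, abs=1e-12)
        assert compute_icc(a, b) < 0.5

    def test_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        a = rng.normal(10, 3, 25)
        b = a + rng.normal(0, 1.5, 25) + 0.7
        df = pd.DataFrame({
            "subj": np.r_[np.arange(25), np.arange(25)],
            "rater": ["A"] * 25 + ["B"] * 25,
            "score": np.r_[a, b],
        })
        tab = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="score")
        ref = float(tab.set_index("Type").loc["ICC(A,1)", "ICC"])
        assert compute_icc(a, b) == pytest.approx(ref, abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            compute_icc([1.0, 2.0], [1.0, 2.0])


class TestRetestFilter:
    def _tables(self, n=30, p=6, seed=0):
        rng = np.random.default_rng(seed)
        scan = pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"F0__r__f__x{i}" for i in range(p)]
        )
        return scan

    def test_exact_copy_retains_all(self):
        scan = self._tables()
        report = retest_filter(scan, scan.copy())
        assert len(report.retained) == scan.shape[1]

    def test_noise_replaced_feature_excluded(self):
        excluded = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            scan = self._tables(seed=seed)
            retest = scan + rng.normal(0, 0.05, scan.shape)
            retest.iloc[:, 2] = rng.normal(size=30)
            report = retest_filter(scan, retest)
            excluded += report.icc.index[2] not in report.retained
        assert excluded >= 48

    def test_impossible_threshold_retains_none(self):
        scan = self._tables()
        report = retest_filter(scan, scan.copy(), threshold=1.01)
        assert report.retained == []

    def test_name_mismatch_rejected(self):
        scan = self._tables()
        bad = scan.rename(columns={scan.columns[0]: "F0__r__f__other"})
        with pytest.raises(ValueError, match="mismatch"):
            retest_filter(scan, bad)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        scan = self._tables(seed=9)
        retest = scan + rng.normal(0, 0.4, scan.shape)
        icc = icc_by_feature(scan, retest)
        prev = None
        for thr in (0.0, 0.5, 0.8, 0.95):
            cur = set(icc.index[icc > thr])
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestDeltaPerDay:
    def test_worked_example(self):
        assert delta_per_day(100.0, 150.0, 50, epsilon=1e-6) == pytest.approx(0.01)

    def test_no_change_is_zero(self):
        for days in (1, 35, 128):
            assert delta_per_day(7.3, 7.3, days, epsilon=1e-6) == 0.0

    def test_zero_baseline_is_missing(self):
        assert np.isnan(delta_per_day(0.0, 5.0, 10, epsilon=1e-6))

    def test_interval_below_one_day_rejected(self):
        with pytest.raises(ValueError):
            delta_per_day(1.0, 2.0, 0, epsilon=0.0)

    @settings(max_examples=200, deadline=None)
    @given(
        f0=finite.filter(lambda x: abs(x) > 1e-3),
        f1=finite.filter(lambda x: abs(x) > 1e-3),
        days=st.integers(min_value=1, max_value=128),
    )
    def test_swap_antisymmetry_identity(self, f0, f1, days):
        fwd = delta_per_day(f0, f1, days, epsilon=0.0)
        bwd = delta_per_day(f1, f0, days, epsilon=0.0)
        assert fwd == pytest.approx(-bwd * (f1 / f0), rel=1e-9, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        f0=finite.filter(lambda x: abs(x) > 1e-3),
        f1=finite.filter(lambda x: abs(x) > 1e-3),
        days=st.integers(min_value=1, max_value=128),
        c=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scaling_invariance(self, f0, f1, days, c):
        base = delta_per_day(f0, f1, days, epsilon=0.0)
        scaled = delta_per_day(c * f0, c * f1, days, epsilon=0.0)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestAssembly:
    def _inputs(self, n=8, k=4, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"P{i}" for i in range(n)]
        base = [f"tumor__fo__x{i}" for i in range(k)]
        f0 = pd.DataFrame(rng.normal(5, 1, (n, k)), index=ids,
                          columns=[f"F0__{b}" for b in base])
        f1 = pd.DataFrame(rng.normal(5, 1, (n, k)), index=ids,
                          columns=[f"F1__{b}" for b in base])
        iv = pd.Series(rng.integers(16, 128, n), index=ids)
        return f0, f1, base, iv

    def test_column_arity(self):
        f0, f1, base, iv = self._inputs()
        table, _ = assemble_feature_table(f0, f1, base, iv)
        assert table.shape[1] == 3 * len(base)  # no f0 near zero here
        assert not table.isna().any().any()

    def test_high_missingness_column_dropped(self):
        f0, f1, base, iv = self._inputs()
        f0[f"F0__{base[0]}"] = 0.0  # every delta for this feature missing
        table, _ = assemble_feature_table(f0, f1, base, iv)
        assert f"delta__{base[0]}" not in table.columns
        assert f"F0__{base[0]}" in table.columns  # timepoint columns stay

    def test_validation_reuses_training_medians(self):
        f0, f1, base, iv = self._inputs(n=10)
        # force one missing delta in training -> imputed by training median
        f0.iloc[0, 0] = 0.0
        table_tr, state = assemble_feature_table(f0, f1, base, iv)
        v0, v1, _, viv = self._inputs(n=6, seed=99)
        v0.iloc[2, 0] = 0.0
        table_va, _ = assemble_feature_table(v0, v1, base, viv, state=state)
        dcol = f"delta__{base[0]}"
        imputed = table_va[dcol].iloc[2]
        assert imputed == pytest.approx(state.impute_medians[dcol])
        # and it is NOT the validation cohort's own median
        others = np.delete(table_va[dcol].to_numpy(), 2)
        assert imputed != pytest.approx(np.median(others))

    def test_patient_missing_timepoint_excluded(self):
        f0, f1, base, iv = self._inputs()
        f1 = f1.drop(index="P3")
        table, _ = assemble_feature_table(f0, f1, base, iv)
        assert "P3" not in table.index and len(table) == 7

    def test_base_name_strips_timepoint(self):
        assert base_name("F0__peri5__glcm__contrast") == "peri5__glcm__contrast"
        assert base_name("delta__tumor__shape__sphericity") == "tumor__shape__sphericity"
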