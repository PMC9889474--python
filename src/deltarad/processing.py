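"""Test-retest reliability filtering, per-day delta features, modeling table.

The reliability statistic is the two-way mixed-effects, single-rater,
absolute-agreement intraclass correlation (ICC(A,1) in the McGraw & Wong
taxonomy), the strict form commonly used for radiomics test-retest: it
penalizes systematic offsets between the two segmentations, not just loss
of rank correlation.  Features with ICC > 0.80 are retained; the decision
is made once per feature name and applied to the baseline, follow-up and
delta versions of the feature alike.

The per-day delta of a feature f is ``(f_F1 - f_F0) / (f_F0 * diff_days)``
— the fractional change per day of the inter-scan interval — and is left
missing when the baseline value is too close to zero for the ratio to be
meaningful (|f_F0| below 1e-8 times the feature's cohort median absolute
value).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "compute_icc",
    "icc_by_feature",
    "ICCReport",
    "retest_filter",
    "delta_per_day",
    "AssemblyState",
    "assemble_feature_table",
    "base_name",
]


def base_name(feature: str) -> str:
    """Strip the timepoint tag: ``F0__tumor__glcm__contrast`` -> ``tumor__glcm__contrast``."""
    return feature.split("__", 1)[1]


# --------------------------------------------------------------------------
# ICC
# --------------------------------------------------------------------------

def compute_icc(measure1, measure2) -> float:
    """ICC(A,1): two-way mixed effects, absolute agreement, single rater.

    From the standard mean-squares decomposition with n subjects and k = 2
    measurements::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

    Identical constant measurements (zero total variance) return 1.0 by
    convention.  Estimates can be negative.
    """
    x = np.column_stack([np.asarray(measure1, float), np.asarray(measure2, float)])
    if x.shape[0] < 3:
        raise ValueError("ICC needs at least 3 paired observations")
    if not np.isfinite(x).all():
        raise ValueError("ICC inputs must be finite")
    return float(_icc_columns(x[:, [0]], x[:, [1]])[0])


def _icc_columns(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Vectorized ICC(A,1) over feature columns; inputs (n_subjects, n_features)."""
    n = m1.shape[0]
    k = 2
    grand = (m1 + m2) / 2  # per-subject means
    col_means = np.vstack([m1.mean(axis=0), m2.mean(axis=0)])  # (2, p)
    overall = col_means.mean(axis=0)
    ssr = k * ((grand - overall) ** 2).sum(axis=0)
    ssc = n * ((col_means - overall) ** 2).sum(axis=0)
    sse = ((m1 - grand - col_means[0] + overall) ** 2).sum(axis=0) + \
          ((m2 - grand - col_means[1] + overall) ** 2).sum(axis=0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msr - mse) / denom
    total_var = msr + msc + mse
    degenerate = total_var <= 1e-300
    if np.any(degenerate):
        log.info("ICC: %d feature(s) with zero total variance -> 1.0 by convention",
                 int(degenerate.sum()))
    return np.where(degenerate, 1.0, icc)


def icc_by_feature(scan: pd.DataFrame, retest: pd.DataFrame) -> pd.Series:
    """Per-feature ICC between two aligned patient x feature tables.

    Patients with a missing value in either table are dropped per feature;
    a feature with < 3 complete pairs gets ICC = NaN.
    """
    if list(scan.columns) != list(retest.columns):
        missing = set(scan.columns) ^ set(retest.columns)
        raise ValueError(f"feature name mismatch between scan and retest tables: {sorted(missing)[:5]}")
    retest = retest.loc[scan.index]
    out = {}
    a = scan.to_numpy(float)
    b = retest.to_numpy(float)
    complete = np.isfinite(a) & np.isfinite(b)
    all_complete = complete.all(axis=0)
    vals = np.full(scan.shape[1], np.nan)
    if all_complete.any():
        vals[all_complete] = _icc_columns(a[:, all_complete], b[:, all_complete])
    for j in np.nonzero(~all_complete)[0]:
        ok = complete[:, j]
        if ok.sum() >= 3:
            vals[j] = _icc_columns(a[ok, j:j + 1], b[ok, j:j + 1])[0]
    return pd.Series(vals, index=scan.columns, name="icc")


@dataclass
class ICCReport:
    """Per-feature ICC values and the retained set at the threshold."""

    icc: pd.Series
    threshold: float
    form: str = "two-way mixed, absolute agreement, single rater (ICC(A,1))"

    @property
    def retained(self) -> list[str]:
        return list(self.icc.index[self.icc > self.threshold])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"icc": self.icc, "retained": self.icc > self.threshold})


def retest_filter(
    features_scan: pd.DataFrame,
    features_retest: pd.DataFrame,
    threshold: float = 0.80,
) -> ICCReport:
    """Exclude features whose test-retest ICC is not above the threshold.

    The retained set is a set of feature *names*: a feature judged stable
    on the baseline re-segmentation is kept for the follow-up and delta
    versions as well.
    """
    if len(features_scan) < 30:
        log.warning("retest filter on only %d patients (30 recommended)", len(features_scan))
    icc = icc_by_feature(features_scan, features_retest)
    report = ICCReport(icc=icc, threshold=threshold)
    log.info("retest filter [%s]: retained %d / %d features at ICC > %.2f",
             report.form, len(report.retained), len(icc), threshold)
    return report


# --------------------------------------------------------------------------
# per-day delta
# --------------------------------------------------------------------------

def delta_per_day(f0: float, f1: float, diff_days: float, epsilon: float) -> float:
    """Per-day fractional change ``(f1 - f0) / (f0 * diff_days)``.

    Returns NaN (missing) when ``|f0| <= epsilon`` — a near-zero baseline
    makes the fractional change meaningless, not infinite.
    """
    if diff_days < 1:
        raise ValueError("inter-scan interval must be >= 1 day")
    if not np.isfinite(f0) or not np.isfinite(f1) or abs(f0) <= epsilon:
        return float("nan")
    return (f1 - f0) / (f0 * diff_days)


# --------------------------------------------------------------------------
# table assembly
# --------------------------------------------------------------------------

@dataclass
class AssemblyState:
    """Training-fitted parameters reused verbatim on the validation cohort."""

    retained_base: list[str]
    epsilon: dict[str, float]            # per base feature, from training F0
    kept_columns: list[str]              # after the missingness cutoff
    impute_medians: dict[str, float]     # training medians
    epsilon_factor: float
    max_missing_fraction: float


def assemble_feature_table(
    f0: pd.DataFrame,
    f1: pd.DataFrame,
    retained_base: list[str],
    intervals: pd.Series,
    state: AssemblyState | None = None,
    epsilon_factor: float = 1e-8,
    max_missing_fraction: float = 0.20,
) -> tuple[pd.DataFrame, AssemblyState]:
    """Build the modeling table: retained F0 + F1 + per-day delta columns.

    When ``state`` is None the call fits on this (training) cohort:
    epsilon guards, the >20%-missing column drop, and imputation medians
    are all derived here and returned for reuse.  When ``state`` is given
    (validation cohort) those parameters are applied unchanged — no
    information flows from validation data into the transform.

    Patients lacking a timepoint or interval are excluded with a log line.
    """
    f0_cols = {base_name(c): c for c in f0.columns}
    f1_cols = {base_name(c): c for c in f1.columns}
    keep_base = [b for b in retained_base if b in f0_cols and b in f1_cols]

    ids = f0.index.intersection(f1.index).intersection(intervals.index)
    dropped = sorted(set(f0.index) | set(f1.index))
    for pid in dropped:
        if pid not in ids:
            log.info("assembly: excluding %s (missing timepoint or interval)", pid)
    f0 = f0.loc[ids]
    f1 = f1.loc[ids]
    days = intervals.loc[ids].to_numpy(float)

    if state is None:
        eps = {
            b: epsilon_factor * float(np.nanmedian(np.abs(f0[f0_cols[b]])))
            for b in keep_base
        }
    else:
        eps = state.epsilon
        keep_base = state.retained_base
        epsilon_factor = state.epsilon_factor
        max_missing_fraction = state.max_missing_fraction

    cols: dict[str, np.ndarray] = {}
    for b in keep_base:
        a0 = f0[f0_cols[b]].to_numpy(float)
        a1 = f1[f1_cols[b]].to_numpy(float)
        cols[f"F0__{b}"] = a0
        cols[f"F1__{b}"] = a1
        guard = eps.get(b, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = (a1 - a0) / (a0 * days)
        d[~np.isfinite(a0) | ~np.isfinite(a1) | (np.abs(a0) <= guard)] = np.nan
        cols[f"delta__{b}"] = d
    table = pd.DataFrame(cols, index=ids)

    if state is None:
        frac_missing = table.isna().mean()
        kept = [c for c in table.columns if frac_missing[c] <= max_missing_fraction]
        for c in table.columns:
            if c not in kept:
                log.info("assembly: dropping %s (%.0f%% missing)", c, 100 * frac_missing[c])
        medians = {c: float(np.nanmedian(table[c])) for c in kept}
        state = AssemblyState(
            retained_base=keep_base,
            epsilon=eps,
            kept_columns=kept,
            impute_medians=medians,
            epsilon_factor=epsilon_factor,
            max_missing_fraction=max_missing_fraction,
        )
    table = table.reindex(columns=state.kept_columns)
    for c in state.kept_columns:
        table[c] = table[c].fillna(state.impute_medians[c])
    # a column can still be all-NaN if its training median was NaN
    bad = [c for c in table.columns if table[c].isna().any()]
    if bad:
        log.warning("assembly: %d column(s) still missing after imputation; filled with 0", len(bad))
        table[bad] = table[bad].fillna(0.0)
    return table, state
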