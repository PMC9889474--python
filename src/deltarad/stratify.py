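"""Risk stratification and prognostic accuracy evaluation.

The signature score is dichotomized at the cutoff maximizing the
two-sample log-rank statistic over all observed scores within a quantile
window (default [0.10, 0.90]) of the training cohort — the maximally
selected log-rank statistic.  Because the cutoff is chosen to maximize
the statistic, the plain log-rank p-value on the resulting split is
anti-conservative; the report states this and additionally carries a
permutation-adjusted p-value (score labels permuted, cutoff re-searched).

Prognostic accuracy at fixed horizons uses the cumulative-cases /
dynamic-controls time-dependent ROC with inverse-probability-of-censoring
weights (Kaplan-Meier censoring estimator).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

log = logging.getLogger(__name__)

__all__ = [
    "StratificationResult",
    "TimeAUC",
    "logrank_statistic",
    "maxstat_cutoff",
    "km_estimate",
    "logrank_test",
    "time_dependent_auc",
    "stratify_and_report",
]


# --------------------------------------------------------------------------
# log-rank machinery
# --------------------------------------------------------------------------

def logrank_statistic(time, event, group) -> float:
    """Two-sample log-rank chi-square statistic (1 df), unweighted.

    ``group`` is a boolean array (True = group 1).  Returns 0 when the
    variance degenerates (e.g. one group empty).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=bool)
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], group[order]
    uniq, start = np.unique(t, return_index=True)
    n = len(t)
    # counts at risk just before each distinct time
    at_risk_total = n - start
    cum_g = np.concatenate([[0], np.cumsum(g)])
    at_risk_g1 = g.sum() - cum_g[start]
    # events at each distinct time
    d_tot = np.zeros(len(uniq))
    d_g1 = np.zeros(len(uniq))
    idx = np.searchsorted(uniq, t[e])
    np.add.at(d_tot, idx, 1)
    idx1 = np.searchsorted(uniq, t[e & g])
    np.add.at(d_g1, idx1, 1)
    keep = d_tot > 0
    nj, n1j, dj, d1j = at_risk_total[keep], at_risk_g1[keep], d_tot[keep], d_g1[keep]
    expected = dj * n1j / nj
    with np.errstate(invalid="ignore", divide="ignore"):
        var = dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / np.maximum(nj - 1, 1)
    V = np.nansum(var)
    if V <= 0:
        return 0.0
    O = d1j.sum()
    E = expected.sum()
    return float((O - E) ** 2 / V)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p-value).

    Raises
    ------
    ValueError
        Unless both groups are nonempty and each contains an event.
    """
    group = np.asarray(group, dtype=bool)
    event = np.asarray(event, dtype=bool)
    for lbl, m in (("group 1", group), ("group 0", ~group)):
        if m.sum() == 0:
            raise ValueError(f"log-rank test needs two nonempty groups ({lbl} empty)")
        if not event[m].any():
            raise ValueError(f"log-rank test needs at least one event per group ({lbl} has none)")
    time = np.asarray(time, dtype=float)
    res = _ll_logrank(time[group], time[~group], event[group], event[~group])
    return float(res.test_statistic), float(res.p_value)


# --------------------------------------------------------------------------
# maximally selected cutoff
# --------------------------------------------------------------------------

@dataclass
class StratificationResult:
    """Cutoff, risk groups and survival summaries for one cohort."""

    cutoff: float
    max_statistic: float
    profile: pd.DataFrame                 # candidate cutoff -> log-rank statistic
    groups: pd.Series | None = None       # patient -> rapid | slow
    median_pfs: dict = field(default_factory=dict)
    logrank_stat: float = np.nan
    logrank_p: float = np.nan
    permutation_p: float = np.nan


def maxstat_cutoff(
    scores,
    time,
    event,
    quantile_range: tuple[float, float] = (0.10, 0.90),
) -> StratificationResult:
    """Maximally selected log-rank cutoff over observed scores.

    Every observed score within the quantile window is a candidate
    threshold (patients with score > threshold form the rapid group); the
    cutoff maximizing the statistic is returned, ties broken toward the
    median score.  The full profile is kept for plotting.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if scores.size < 20:
        raise ValueError("cutoff search needs at least 20 patients")
    if event.sum() < 10:
        raise ValueError("cutoff search needs at least 10 events")
    lo, hi = np.quantile(scores, quantile_range)
    cand = np.unique(scores[(scores >= lo) & (scores <= hi) & (scores < scores.max())])
    if cand.size == 0:
        raise ValueError("no candidate cutoffs inside the quantile range")
    stats = np.array([logrank_statistic(time, event, scores > c) for c in cand])
    best = stats.max()
    ties = cand[stats >= best - 1e-12]
    cutoff = float(ties[np.argmin(np.abs(ties - np.median(scores)))])
    return StratificationResult(
        cutoff=cutoff,
        max_statistic=float(best),
        profile=pd.DataFrame({"cutoff": cand, "statistic": stats}),
    )


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

def km_estimate(time, event, group_labels) -> dict:
    """Product-limit survival curve and median PFS per group.

    The median is the first time at which S(t) <= 0.5 (right-continuous
    step convention); NaN when the curve never reaches 0.5.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    labels = pd.Series(group_labels).reset_index(drop=True)
    out = {}
    for lbl in labels.unique():
        m = (labels == lbl).to_numpy()
        if m.sum() == 0:
            continue
        km = KaplanMeierFitter()
        km.fit(time[m], event[m], label=str(lbl))
        med = km.median_survival_time_
        out[str(lbl)] = {
            "n": int(m.sum()),
            "events": int(event[m].sum()),
            "times": km.survival_function_.index.to_numpy().tolist(),
            "survival": km.survival_function_.iloc[:, 0].to_numpy().tolist(),
            "median": float(med) if np.isfinite(med) else float("nan"),
        }
    return out


# --------------------------------------------------------------------------
# time-dependent ROC
# --------------------------------------------------------------------------

@dataclass
class TimeAUC:
    horizons: tuple
    auc: dict                 # horizon -> AUC
    ci: dict                  # horizon -> (lo, hi)


def time_dependent_auc(
    scores,
    time,
    event,
    horizons=(6.0, 9.0, 12.0),
    n_boot: int = 200,
    seed: int = 0,
    min_cases: int = 5,
) -> TimeAUC:
    """Cumulative/dynamic AUC(t) with IPCW at fixed horizons (months).

    Cases at horizon t are patients with an observed event by t, controls
    those still event-free at t; censoring is weighted out with the
    Kaplan-Meier censoring-survival estimator of the same cohort.

    Raises
    ------
    ValueError
        If a horizon exceeds the follow-up support or has fewer than
        ``min_cases`` cases or controls.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    for h in horizons:
        if h >= time.max():
            raise ValueError(f"horizon {h} months is beyond the follow-up support ({time.max():.1f})")
        cases = int(((time <= h) & event).sum())
        controls = int((time > h).sum())
        if cases < min_cases or controls < min_cases:
            raise ValueError(
                f"horizon {h} months has {cases} cases / {controls} controls "
                f"(need >= {min_cases} each)"
            )
    y = Surv.from_arrays(event, time)
    aucs, _ = cumulative_dynamic_auc(y, y, scores, np.asarray(horizons, dtype=float))
    rng = np.random.default_rng(seed)
    boots = {h: [] for h in horizons}
    n = len(scores)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        tb, eb, sb = time[idx], event[idx], scores[idx]
        try:
            yb = Surv.from_arrays(eb, tb)
            ab, _ = cumulative_dynamic_auc(yb, yb, sb, np.asarray(horizons, dtype=float))
        except (ValueError, ZeroDivisionError):
            continue
        for h, a in zip(horizons, ab):
            if np.isfinite(a):
                boots[h].append(a)
    ci = {
        h: tuple(np.percentile(boots[h], [2.5, 97.5])) if len(boots[h]) >= 20 else (np.nan, np.nan)
        for h in horizons
    }
    return TimeAUC(
        horizons=tuple(horizons),
        auc={h: float(a) for h, a in zip(horizons, aucs)},
        ci={h: (float(a), float(b)) for h, (a, b) in ci.items()},
    )


# --------------------------------------------------------------------------
# full stratification report
# --------------------------------------------------------------------------

def _stratify_cohort(result: StratificationResult, scores, time, event,
                     ids, cohort_name: str) -> StratificationResult:
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    rapid = scores > result.cutoff
    res = StratificationResult(
        cutoff=result.cutoff,
        max_statistic=result.max_statistic,
        profile=result.profile,
        groups=pd.Series(np.where(rapid, "rapid", "slow"), index=ids),
    )
    if rapid.sum() == 0 or (~rapid).sum() == 0:
        log.warning("%s cohort: one risk group empty at cutoff %.2f; "
                    "group-level statistics suppressed", cohort_name, result.cutoff)
        return res
    km = km_estimate(time, event, res.groups.to_numpy())
    res.median_pfs = {g: km[g]["median"] for g in km}
    try:
        res.logrank_stat, res.logrank_p = logrank_test(time, event, rapid)
    except ValueError as exc:
        log.warning("%s cohort: log-rank unavailable (%s)", cohort_name, exc)
    return res


def stratify_and_report(
    scores_train,
    scores_valid,
    outcomes_train: pd.DataFrame,
    outcomes_valid: pd.DataFrame,
    horizons=(6.0, 9.0, 12.0),
    quantile_range=(0.10, 0.90),
    out_dir: str | Path | None = None,
    seed: int = 0,
    n_permutations: int = 200,
    n_boot: int = 200,
) -> dict:
    """Train-fitted cutoff applied unchanged to validation; KM + tdROC report.

    Outcome frames need ``pfs_months`` and ``event`` columns indexed by
    patient.  Writes ``report.json`` and plots when ``out_dir`` is given;
    returns the report dict.
    """
    tr_t = outcomes_train["pfs_months"].to_numpy(float)
    tr_e = outcomes_train["event"].to_numpy(bool)
    va_t = outcomes_valid["pfs_months"].to_numpy(float)
    va_e = outcomes_valid["event"].to_numpy(bool)
    scores_train = np.asarray(scores_train, dtype=float)
    scores_valid = np.asarray(scores_valid, dtype=float)

    base = maxstat_cutoff(scores_train, tr_t, tr_e, quantile_range)
    rng = np.random.default_rng(seed)
    perm_stats = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(scores_train))
        perm_stats.append(
            maxstat_cutoff(scores_train[perm], tr_t, tr_e, quantile_range).max_statistic
        )
    perm_p = (1 + np.sum(np.asarray(perm_stats) >= base.max_statistic)) / (n_permutations + 1)

    train = _stratify_cohort(base, scores_train, tr_t, tr_e, outcomes_train.index, "training")
    train.permutation_p = float(perm_p)
    valid = _stratify_cohort(base, scores_valid, va_t, va_e, outcomes_valid.index, "validation")

    km_train = km_estimate(tr_t, tr_e, train.groups.to_numpy())
    km_valid = (
        km_estimate(va_t, va_e, valid.groups.to_numpy())
        if valid.groups is not None and valid.groups.nunique() == 2 else {}
    )
    auc_train = time_dependent_auc(scores_train, tr_t, tr_e, horizons, n_boot=n_boot, seed=seed)
    auc_valid = time_dependent_auc(scores_valid, va_t, va_e, horizons, n_boot=n_boot, seed=seed + 1)

    report = {
        "cutoff": train.cutoff,
        "max_logrank_statistic": train.max_statistic,
        "note": (
            "The log-rank p-value below is computed on the split that maximizes "
            "the statistic and is therefore anti-conservative; see the "
            "permutation-adjusted p-value."
        ),
        "train": {
            "median_pfs": train.median_pfs,
            "logrank_statistic": train.logrank_stat,
            "logrank_p": train.logrank_p,
            "logrank_p_permutation_adjusted": train.permutation_p,
            "groups": train.groups.value_counts().to_dict(),
            "tdAUC": {str(h): auc_train.auc[h] for h in horizons},
            "tdAUC_ci": {str(h): auc_train.ci[h] for h in horizons},
        },
        "valid": {
            "median_pfs": valid.median_pfs,
            "logrank_statistic": valid.logrank_stat,
            "logrank_p": valid.logrank_p,
            "groups": valid.groups.value_counts().to_dict(),
            "tdAUC": {str(h): auc_valid.auc[h] for h in horizons},
            "tdAUC_ci": {str(h): auc_valid.ci[h] for h in horizons},
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        _plots(out, base, km_train, km_valid, auc_train, auc_valid,
               scores_train, tr_t, tr_e, scores_valid, va_t, va_e, horizons)
    return report


def _plots(out, base, km_train, km_valid, auc_train, auc_valid,
           s_tr, t_tr, e_tr, s_va, t_va, e_va, horizons) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(base.profile["cutoff"], base.profile["statistic"], lw=1)
    ax.axvline(base.cutoff, color="r", ls="--", label=f"cutoff = {base.cutoff:.2f}")
    ax.set_xlabel("signature score cutoff")
    ax.set_ylabel("log-rank statistic")
    ax.legend()
    fig.savefig(out / "maxstat_profile.png", dpi=100)
    plt.close(fig)

    for name, km in (("km_train.png", km_train), ("km_valid.png", km_valid)):
        if not km:
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        for g, d in km.items():
            ax.step(d["times"], d["survival"], where="post",
                    label=f"{g} (n={d['n']}, median={d['median']:.1f} mo)")
        ax.set_xlabel("months")
        ax.set_ylabel("PFS probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        fig.savefig(out / name, dpi=100)
        plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, (label, auc) in zip(axes, (("training", auc_train), ("validation", auc_valid))):
        hs = list(auc.auc)
        ax.plot(hs, [auc.auc[h] for h in hs], "o-")
        for h in hs:
            lo, hi = auc.ci[h]
            ax.plot([h, h], [lo, hi], color="gray", lw=1)
        ax.axhline(0.5, color="k", ls=":")
        ax.set_title(label)
        ax.set_xlabel("horizon (months)")
    axes[0].set_ylabel("cumulative/dynamic AUC")
    fig.savefig(out / "tdroc.png", dpi=100)
    plt.close(fig)
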