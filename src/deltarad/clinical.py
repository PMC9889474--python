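"""Cox baselines, Harrell's C-index and paired model comparison.

Conventions fixed here and used throughout the package:

* Cox partial likelihood uses Efron tie handling (the lifelines default).
* A pair of patients is comparable for the C-index iff the shorter observed
  time is an event; pairs with exactly tied times are not comparable.
* Tied risk predictions receive 0.5 concordance credit.
* Model comparison is a paired patient-level bootstrap of the C-index
  difference with the (+1)/(B+1) small-sample correction.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

log = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "cox_univariate",
    "cox_forward_aic",
    "combine_clinico_radiomics",
    "harrell_c",
    "harrell_c_ci",
    "compare_c_paired",
]


# --------------------------------------------------------------------------
# Harrell's C
# --------------------------------------------------------------------------

def _pair_matrices(time: np.ndarray, event: np.ndarray, risk: np.ndarray):
    """(comparable, concordance-credit) matrices over ordered patient pairs.

    ``W[i, j] = 1`` iff patient i has the shorter time and an event;
    ``M[i, j]`` is W times the credit (1 correct order, 0.5 risk tie).
    """
    t = time[:, None]
    W = ((t < time[None, :]) & event[:, None]).astype(float)
    r = risk[:, None]
    credit = np.where(r > risk[None, :], 1.0, np.where(r == risk[None, :], 0.5, 0.0))
    return W, W * credit


def harrell_c(risk, time, event) -> float:
    """Harrell's concordance index: concordant / comparable pairs.

    Raises
    ------
    ValueError
        If there are no comparable pairs.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    W, M = _pair_matrices(time, event, risk)
    denom = W.sum()
    if denom == 0:
        raise ValueError("no comparable pairs (check event indicators)")
    return float(M.sum() / denom)


def _bootstrap_quadratic(W, M, n_boot, seed):
    """Bootstrap C-index values via quadratic forms over multiplicity vectors.

    Resampling patients with replacement multiplies pair (i, j) by
    ``m_i * m_j`` where ``m`` is the resample multiplicity; the bootstrap
    C-index is then ``m' M m / m' W m`` without re-enumerating pairs.
    """
    n = W.shape[0]
    rng = np.random.default_rng(seed)
    B = np.zeros((n_boot, n))
    idx = rng.integers(0, n, size=(n_boot, n))
    for b in range(n_boot):
        B[b] = np.bincount(idx[b], minlength=n)
    num = np.einsum("bi,ij,bj->b", B, M, B, optimize=True)
    den = np.einsum("bi,ij,bj->b", B, W, B, optimize=True)
    ok = den > 0
    return num[ok] / den[ok], B, ok


def harrell_c_ci(risk, time, event, n_boot: int = 1000, seed: int = 0):
    """C-index with a percentile-bootstrap 95% CI over patients."""
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    c = harrell_c(risk, time, event)
    W, M = _pair_matrices(time, event, risk)
    cs, _, _ = _bootstrap_quadratic(W, M, n_boot, seed)
    lo, hi = np.percentile(cs, [2.5, 97.5])
    return c, (float(lo), float(hi))


def compare_c_paired(risk1, risk2, time, event, n_boot: int = 2000, seed: int = 0) -> float:
    """Two-sided p-value for C(model1) = C(model2) on the same patients.

    Paired patient-level bootstrap of ``dC = C1 - C2``:
    ``p = 2 * min(P(dC* <= 0), P(dC* >= 0))`` with the (+1)/(B+1)
    correction, capped at 1.  Returns 1.0 when the difference is
    degenerate at zero (identical predictions).
    """
    risk1 = np.asarray(risk1, dtype=float)
    risk2 = np.asarray(risk2, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    W, M1 = _pair_matrices(time, event, risk1)
    _, M2 = _pair_matrices(time, event, risk2)
    c1, B, ok = _bootstrap_quadratic(W, M1, n_boot, seed)
    num2 = np.einsum("bi,ij,bj->b", B, M2, B, optimize=True)[ok]
    den = np.einsum("bi,ij,bj->b", B, W, B, optimize=True)[ok]
    dc = c1 - num2 / den
    if np.all(dc == 0):
        return 1.0
    b = dc.size
    p_le = (1 + np.sum(dc <= 0)) / (b + 1)
    p_ge = (1 + np.sum(dc >= 0)) / (b + 1)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# --------------------------------------------------------------------------
# Cox regression
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted (or flagged) Cox proportional-hazards model."""

    covariates: list[str]                    # design-matrix column names
    coef: dict[str, float] = field(default_factory=dict)
    hr: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    log_likelihood: float = np.nan
    aic: float = np.nan
    converged: bool = True
    note: str = ""
    model: CoxPHFitter | None = None

    def linear_predictor(self, design: pd.DataFrame) -> np.ndarray:
        if self.model is None:
            return np.zeros(len(design))
        X = design.reindex(columns=self.covariates, fill_value=0.0)
        return self.model.predict_log_partial_hazard(X).to_numpy()


def expand_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categorical covariates against the first (reference) level.

    Reference level = first in sorted category order; numeric columns pass
    through unchanged.
    """
    blocks = []
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            blocks.append(s.astype(float).to_frame())
        else:
            cats = sorted(s.astype(str).unique())
            d = pd.get_dummies(pd.Categorical(s.astype(str), categories=cats),
                               prefix=col, dtype=float).iloc[:, 1:]
            d.index = s.index
            blocks.append(d)
    return pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=covariates.index)


def _fit_cox(design: pd.DataFrame, time, event) -> CoxFit:
    df = design.copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=int)
    # constant columns carry no information and break the fit: drop them,
    # flag the model only if nothing informative remains
    names = [c for c in design.columns]
    constant = [c for c in names if design[c].var() == 0.0]
    if constant:
        log.info("Cox fit: dropping constant covariate(s) %s", constant)
        names = [c for c in names if c not in constant]
        df = df.drop(columns=constant)
        design = design[names]
    if not names:
        return CoxFit(covariates=[], converged=False, note="constant covariate")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except (ConvergenceError, Exception) as exc:  # separation, singularities
        return CoxFit(covariates=names, converged=False, note=f"fit failed: {exc}")
    summ = cph.summary
    ll = float(cph.log_likelihood_)
    k = len(names)
    return CoxFit(
        covariates=names,
        coef={c: float(summ.loc[c, "coef"]) for c in names},
        hr={c: float(summ.loc[c, "exp(coef)"]) for c in names},
        ci={
            c: (float(summ.loc[c, "exp(coef) lower 95%"]),
                float(summ.loc[c, "exp(coef) upper 95%"]))
            for c in names
        },
        p={c: float(summ.loc[c, "p"]) for c in names},
        log_likelihood=ll,
        aic=2 * k - 2 * ll,
        model=cph,
    )


def _null_log_likelihood(fit: CoxFit) -> float:
    """Null (beta = 0) partial log-likelihood recovered from a fitted model."""
    stat = fit.model.log_likelihood_ratio_test().test_statistic
    return fit.log_likelihood - stat / 2.0


def cox_univariate(covariate: pd.Series, time, event) -> CoxFit:
    """Univariate Cox fit; categorical covariates expanded against a
    reference level.  Non-convergence or a constant covariate yields a
    flagged (``converged=False``) fit rather than an exception."""
    event = np.asarray(event, dtype=bool)
    if event.sum() < 10:
        log.warning("univariate Cox with only %d events", int(event.sum()))
    design = expand_design(covariate.to_frame())
    return _fit_cox(design, time, event)


def cox_forward_aic(covariates: pd.DataFrame, time, event) -> CoxFit:
    """Greedy forward covariate selection by AIC.

    Starts from the null model; at each step adds the covariate (as a
    block: a categorical enters with all its dummy columns) that lowers
    AIC the most; stops when no addition lowers it.  Among AIC ties
    (<1e-6) the model with fewer parameters is preferred, i.e. the
    addition is not made.  Returns the selected model (possibly null).
    """
    if covariates.shape[1] < 2:
        raise ValueError("need at least 2 candidate covariates")
    blocks = {c: expand_design(covariates[[c]]) for c in covariates.columns}

    # null model AIC via any single successful fit
    ll0 = None
    for c, b in blocks.items():
        f = _fit_cox(b, time, event)
        if f.converged:
            ll0 = _null_log_likelihood(f)
            break
    if ll0 is None:
        return CoxFit(covariates=[], converged=False, note="no covariate fit converged")

    selected: list[str] = []
    current_aic = -2 * ll0
    current_fit = CoxFit(covariates=[], log_likelihood=ll0, aic=current_aic)
    while True:
        best = None
        for c in covariates.columns:
            if c in selected:
                continue
            design = pd.concat([blocks[s] for s in selected + [c]], axis=1)
            fit = _fit_cox(design, time, event)
            if not fit.converged:
                log.info("forward AIC: skipping %s (%s)", c, fit.note)
                continue
            if best is None or fit.aic < best[1].aic:
                best = (c, fit)
        if best is None or best[1].aic >= current_aic - 1e-6:
            break
        selected.append(best[0])
        current_aic = best[1].aic
        current_fit = best[1]
    current_fit.note = f"forward-AIC selected: {selected}"
    return current_fit


def combine_clinico_radiomics(
    scores, clinical_design: pd.DataFrame | None, time, event
) -> CoxFit:
    """Cox fit on [signature score + selected clinical covariates]."""
    scores = np.asarray(scores, dtype=float)
    design = pd.DataFrame({"signature_score": scores})
    if clinical_design is not None and clinical_design.shape[1] > 0:
        design = pd.concat(
            [design, clinical_design.reset_index(drop=True)], axis=1
        )
    return _fit_cox(design, time, event)
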