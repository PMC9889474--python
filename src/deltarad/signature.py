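"""Radiomics signature construction: survival forests, Boruta, risk scores.

The signature is built in three steps, all on the training cohort only:

1. a random survival forest (log-rank splitting, sqrt(p) candidate
   features per split) provides out-of-bag (OOB) risk predictions,
2. feature relevance is decided by the Boruta scheme — every candidate
   competes against "shadow" copies of the whole table with permuted
   rows, and a feature is confirmed/rejected by a Bonferroni-corrected
   binomial test on how often it beats the best shadow,
3. the top-k (default 10) features by importance are refit into the final
   forest, whose ensemble mortality, min-max scaled to [0, 100] on the
   training cohort, is the signature score.

Importance is the drop in OOB concordance when a feature column is
permuted: the forest is never refit, only re-evaluated, and only trees
that actually split on the feature are re-applied.

Three feature pools mirror the ablations of interest: ``all`` (baseline +
follow-up + delta, all regions), ``baseline`` (F0 columns only) and
``intratumor`` (tumor-region columns only, any timepoint).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import _forest as _sk_forest
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .clinical import harrell_c

log = logging.getLogger(__name__)

__all__ = [
    "RSFModel",
    "fit_survival_forest",
    "permutation_importance",
    "SelectionResult",
    "boruta_select",
    "SignatureModel",
    "build_signature",
    "signature_score",
    "pool_columns",
]


# --------------------------------------------------------------------------
# random survival forest with OOB bookkeeping
# --------------------------------------------------------------------------

@dataclass
class RSFModel:
    """A fitted survival forest plus its out-of-bag machinery.

    ``oob_risk`` is the ensemble mortality of each training patient
    averaged over the trees for which the patient was out-of-bag; it is
    NaN for patients in-bag everywhere (vanishingly rare beyond ~50
    trees).  ``tree_risk`` caches per-(tree, patient) predictions so a
    permuted column only requires re-applying the trees that use it.
    """

    forest: RandomSurvivalForest
    feature_names: list[str]
    seed: int
    oob_risk: np.ndarray = field(repr=False)
    oob_cindex: float
    tree_risk: np.ndarray = field(repr=False)        # (n_trees, n) NaN when in-bag
    leaf_risk: list[np.ndarray] = field(repr=False)  # per tree: node id -> risk
    oob_sets: list[np.ndarray] = field(repr=False)
    tree_features: list[np.ndarray] = field(repr=False)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.forest.predict(X)


def _tree_leaf_risk(tree, X32: np.ndarray) -> np.ndarray:
    """Map every tree node to its risk (ensemble-mortality) prediction."""
    leaves = tree.tree_.apply(X32)
    risks = tree.predict(X32)
    out = np.zeros(tree.tree_.node_count)
    out[leaves] = risks
    return out


def fit_survival_forest(
    X,
    time,
    event,
    n_trees: int = 500,
    seed: int = 0,
    min_samples_leaf: int = 6,
    max_features: str | float = "sqrt",
) -> RSFModel:
    """Fit a random survival forest and compute OOB risks.

    Trees are grown on bootstrap samples with the log-rank split
    criterion.  The risk score is the ensemble mortality (sum of the
    cumulative hazard over the event times).  Deterministic given the
    seed.

    Raises
    ------
    ValueError
        For missing values in ``X`` or all-censored outcomes.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.asarray(X).shape[1])]
    Xa = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if not np.isfinite(Xa).all():
        raise ValueError("feature table contains missing values; impute before fitting")
    if event.sum() == 0:
        raise ValueError("cannot fit a survival forest on all-censored outcomes")
    if event.sum() < 20:
        log.warning("survival forest with only %d events", int(event.sum()))
    y = Surv.from_arrays(event, time)
    forest = RandomSurvivalForest(
        n_estimators=n_trees,
        max_features=max_features,
        min_samples_leaf=min_samples_leaf,
        bootstrap=True,
        n_jobs=1,
        random_state=int(seed),
    )
    forest.fit(Xa, y)

    n = Xa.shape[0]
    X32 = np.ascontiguousarray(Xa, dtype=np.float32)
    n_boot = _sk_forest._get_n_samples_bootstrap(n, forest.max_samples, None)
    tree_risk = np.full((n_trees, n), np.nan)
    leaf_risk: list[np.ndarray] = []
    oob_sets: list[np.ndarray] = []
    tree_features: list[np.ndarray] = []
    for t, est in enumerate(forest.estimators_):
        oob = _sk_forest._generate_unsampled_indices(est.random_state, n, n_boot, None)
        lr = _tree_leaf_risk(est, X32)
        leaf_risk.append(lr)
        oob_sets.append(oob)
        tree_features.append(np.unique(est.tree_.feature[est.tree_.feature >= 0]))
        if oob.size:
            tree_risk[t, oob] = lr[est.tree_.apply(X32[oob])]
    with np.errstate(invalid="ignore"):
        oob_risk = np.nanmean(tree_risk, axis=0)
    defined = np.isfinite(oob_risk)
    oob_c = harrell_c(oob_risk[defined], time[defined], event[defined])
    return RSFModel(
        forest=forest,
        feature_names=names,
        seed=int(seed),
        oob_risk=oob_risk,
        oob_cindex=float(oob_c),
        tree_risk=tree_risk,
        leaf_risk=leaf_risk,
        oob_sets=oob_sets,
        tree_features=tree_features,
    )


def permutation_importance(
    model: RSFModel,
    X,
    time,
    event,
    n_repeats: int = 1,
    seed: int = 0,
    features: list[int] | None = None,
) -> np.ndarray:
    """Permutation importance: mean drop in OOB C-index per permuted feature.

    Only trees that split on the permuted feature are re-applied; the rest
    reuse their cached OOB predictions.  A constant column yields exactly
    zero importance.
    """
    Xa = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    rng = np.random.default_rng(seed)
    n_trees, n = model.tree_risk.shape
    p = Xa.shape[1]
    todo = range(p) if features is None else features
    base_c = model.oob_cindex
    uses = [
        [t for t in range(n_trees) if j in model.tree_features[t]]
        for j in range(p)
    ]
    imps = np.zeros(p)
    for j in todo:
        if not uses[j] or np.all(Xa[:, j] == Xa[0, j]):
            imps[j] = 0.0
            continue
        drops = []
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            Xp = Xa.copy()
            Xp[:, j] = Xa[perm, j]
            Xp32 = np.ascontiguousarray(Xp, dtype=np.float32)
            risk = model.tree_risk.copy()
            for t in uses[j]:
                oob = model.oob_sets[t]
                if oob.size:
                    est = model.forest.estimators_[t]
                    risk[t, oob] = model.leaf_risk[t][est.tree_.apply(Xp32[oob])]
            with np.errstate(invalid="ignore"):
                oob_risk = np.nanmean(risk, axis=0)
            ok = np.isfinite(oob_risk)
            drops.append(base_c - harrell_c(oob_risk[ok], time[ok], event[ok]))
        imps[j] = float(np.mean(drops))
    return imps


def tree_permutation_importance(
    model: RSFModel,
    X,
    time,
    event,
    seed: int = 0,
) -> np.ndarray:
    """Breiman-style per-tree OOB permutation importance.

    For every tree that splits on a feature, the feature column is
    permuted within the tree's OOB sample and the drop in that tree's
    OOB concordance is recorded; the importance is the summed drop
    divided by the number of trees.

    This is the importance used inside the Boruta loop: unlike the
    ensemble-level drop (:func:`permutation_importance`), it stays
    informative for groups of correlated features — an individual tree
    often lacks the correlates that would otherwise mask the permuted
    feature at the ensemble level.
    """
    Xa = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    rng = np.random.default_rng(seed)
    n_trees, n = model.tree_risk.shape
    p = Xa.shape[1]
    X32 = np.ascontiguousarray(Xa, dtype=np.float32)
    base: list[tuple[float, np.ndarray] | None] = []
    for t in range(n_trees):
        oob = model.oob_sets[t]
        try:
            c0 = harrell_c(model.tree_risk[t, oob], time[oob], event[oob])
        except (ValueError, IndexError):
            base.append(None)
            continue
        base.append((c0, oob))
    users: dict[int, list[int]] = {j: [] for j in range(p)}
    for t in range(n_trees):
        if base[t] is None:
            continue
        for j in model.tree_features[t]:
            if j < p:
                users[int(j)].append(t)
    imps = np.zeros(p)
    for j in range(p):
        tot = 0.0
        for t in users[j]:
            c0, oob = base[t]
            Xp = X32[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            est = model.forest.estimators_[t]
            pred = model.leaf_risk[t][est.tree_.apply(Xp)]
            tot += c0 - harrell_c(pred, time[oob], event[oob])
        imps[j] = tot / n_trees
    return imps


# --------------------------------------------------------------------------
# Boruta
# --------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of the Boruta run over one candidate pool.

    ``tentative`` holds the undecided features whose median importance
    beat the median best-shadow importance in the rough-fix pass;
    undecided features below that bar are moved to ``rejected``.  The
    three sets partition the candidate set.
    """

    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    importance_history: pd.DataFrame      # iterations x candidates (NaN once dropped)
    shadow_max_history: list[float]
    final_importance: pd.Series           # median importance over iterations
    n_iterations: int


def boruta_select(
    X: pd.DataFrame,
    time,
    event,
    max_iter: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    n_trees: int = 100,
    min_samples_leaf: int = 6,
) -> SelectionResult:
    """All-relevant feature selection around the survival forest.

    Each iteration appends a shadow (row-permuted) copy of every active
    candidate, fits a forest on the joint table, and scores a "hit" for
    candidates whose per-tree OOB permutation importance
    (:func:`tree_permutation_importance`) exceeds the best shadow's.
    Two-sided binomial tests (p = 0.5) with Bonferroni correction over the
    full candidate set confirm or reject features; rejected features leave
    the table.  Runs until every feature is decided or ``max_iter``.
    """
    if max_iter < 5:
        raise ValueError("max_iter < 5 leaves the binomial test powerless")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    rng = np.random.default_rng(seed)
    candidates = list(X.columns)
    n_cand = len(candidates)
    active = list(candidates)
    confirmed: list[str] = []
    rejected: list[str] = []
    hits = dict.fromkeys(candidates, 0)
    trials = 0
    history: list[dict[str, float]] = []
    shadow_max_hist: list[float] = []
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)

    for it in range(max_iter):
        if not active:
            break
        Xa = X[active].to_numpy(float)
        n, p = Xa.shape
        shadows = np.column_stack([Xa[rng.permutation(n), j] for j in range(p)])
        joint = np.concatenate([Xa, shadows], axis=1)
        model = fit_survival_forest(
            joint, time, event,
            n_trees=n_trees, seed=int(rng.integers(0, 2**31 - 1)),
            min_samples_leaf=min_samples_leaf,
        )
        imps = tree_permutation_importance(
            model, joint, time, event, seed=int(rng.integers(0, 2**31 - 1)),
        )
        real, shadow = imps[:p], imps[p:]
        shadow_max = float(shadow.max())
        shadow_max_hist.append(shadow_max)
        history.append({f: float(v) for f, v in zip(active, real)})
        trials += 1
        for f, v in zip(active, real):
            if v > shadow_max:
                hits[f] += 1
        # Bonferroni-corrected binomial decisions over the full candidate set
        newly_rejected = []
        for f in list(active):
            bt_g = binomtest(hits[f], trials, 0.5, alternative="greater").pvalue
            bt_l = binomtest(hits[f], trials, 0.5, alternative="less").pvalue
            if bt_g * n_cand < alpha:
                confirmed.append(f)
                active.remove(f)
            elif bt_l * n_cand < alpha:
                rejected.append(f)
                newly_rejected.append(f)
                active.remove(f)
        if newly_rejected:
            log.info("boruta iter %d: rejected %d, confirmed so far %d",
                     it + 1, len(newly_rejected), len(confirmed))

    imp_hist = pd.DataFrame(history, columns=candidates)
    final_importance = imp_hist.median(axis=0, skipna=True).fillna(0.0)
    # rough fix for the undecided: compare median importance against the
    # median best-shadow importance
    med_shadow = float(np.median(shadow_max_hist)) if shadow_max_hist else 0.0
    tentative = []
    for f in active:
        if final_importance[f] > med_shadow:
            tentative.append(f)
        else:
            rejected.append(f)
    log.info("boruta: %d confirmed, %d rejected, %d tentative after %d iterations",
             len(confirmed), len(rejected), len(tentative), trials)
    return SelectionResult(
        confirmed=confirmed,
        rejected=rejected,
        tentative=tentative,
        importance_history=imp_hist,
        shadow_max_history=shadow_max_hist,
        final_importance=final_importance,
        n_iterations=trials,
    )


# --------------------------------------------------------------------------
# signature pools and models
# --------------------------------------------------------------------------

def pool_columns(columns: list[str], pool: str) -> list[str]:
    """Restrict structured feature names to a signature pool.

    ``all``: every column; ``baseline``: F0 columns only;
    ``intratumor``: tumor-region columns (any timepoint, incl. delta).
    """
    if pool == "all":
        return list(columns)
    if pool == "baseline":
        return [c for c in columns if c.startswith("F0__")]
    if pool == "intratumor":
        return [c for c in columns if c.split("__")[1] == "tumor"]
    raise ValueError(f"unknown pool {pool!r} (expected all|baseline|intratumor)")


@dataclass
class SignatureModel:
    """A fitted radiomics signature: top-k forest plus score scaling."""

    pool: str
    features: list[str]
    rsf: RSFModel
    score_min: float
    score_max: float
    selection: SelectionResult = field(repr=False)

    def score(self, X: pd.DataFrame) -> np.ndarray:
        return signature_score(self, X)


def build_signature(
    table: pd.DataFrame,
    time,
    event,
    pool: str = "all",
    k: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    boruta_n_trees: int = 100,
    boruta_max_iter: int = 50,
    boruta_alpha: float = 0.05,
    min_samples_leaf: int = 6,
) -> SignatureModel:
    """Select the top-k features for a pool and fit the signature forest.

    Confirmed features are ranked by final importance (ties broken by
    name), topped up from the tentative set when fewer than ``k`` were
    confirmed; if still short, the signature proceeds with what was
    decidable and logs a warning.  The ensemble mortality of the refit
    forest is min-max scaled to [0, 100] on the training cohort.
    """
    cols = pool_columns(list(table.columns), pool)
    if len(cols) < k:
        log.warning("pool %s has only %d candidate features (< k=%d)", pool, len(cols), k)
    rng = np.random.default_rng(seed)
    sel = boruta_select(
        table[cols], time, event,
        max_iter=boruta_max_iter, alpha=boruta_alpha,
        seed=int(rng.integers(0, 2**31 - 1)),
        n_trees=boruta_n_trees, min_samples_leaf=min_samples_leaf,
    )

    def ranked(names: list[str]) -> list[str]:
        return sorted(names, key=lambda f: (-sel.final_importance[f], f))

    chosen = ranked(sel.confirmed)[:k]
    if len(chosen) < k:
        extra = ranked(sel.tentative)[: k - len(chosen)]
        chosen += extra
    if len(chosen) < k:
        log.warning("pool %s: only %d decidable features (wanted %d)", pool, len(chosen), k)
    if not chosen:
        # an uninformative pool: Boruta rejects everything, but the pool's
        # signature is still wanted as a comparison arm, so fall back to the
        # k nominally most important candidates
        log.warning("pool %s: no feature decidable; falling back to top-%d by importance", pool, k)
        chosen = ranked(cols)[:k]
    rsf = fit_survival_forest(
        table[chosen], time, event,
        n_trees=n_trees, seed=int(rng.integers(0, 2**31 - 1)),
        min_samples_leaf=min_samples_leaf,
    )
    raw = rsf.predict(table[chosen])
    lo, hi = float(raw.min()), float(raw.max())
    if hi <= lo:
        hi = lo + 1.0
    return SignatureModel(
        pool=pool, features=chosen, rsf=rsf,
        score_min=lo, score_max=hi, selection=sel,
    )


def signature_score(model: SignatureModel, X: pd.DataFrame) -> np.ndarray:
    """Per-patient signature score on the 0-100 training scale.

    Out-of-range predictions on new data are clamped to [0, 100] with a
    warning.  A missing feature raises immediately, naming it.
    """
    missing = [f for f in model.features if f not in X.columns]
    if missing:
        raise KeyError(f"feature table lacks signature feature(s): {missing}")
    raw = model.rsf.predict(X[model.features])
    score = 100.0 * (raw - model.score_min) / (model.score_max - model.score_min)
    if np.any(score < 0) or np.any(score > 100):
        log.warning("signature scores outside [0, 100] clamped (new data beyond training range)")
        score = np.clip(score, 0.0, 100.0)
    return score
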