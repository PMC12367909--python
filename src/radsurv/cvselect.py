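"""Feature selection for survival radiomics with stability ranking.

Two unsupervised screens (tumour-volume confounding by Spearman
correlation, pairwise redundancy by Pearson correlation) are followed by
three supervised selectors — univariable Cox significance, added value
over a clinical Cox model by likelihood-ratio test, and a greedy
minimum-redundancy maximum-relevance (MRMR) ranking — each run over 200
event-matched stratified cross-validation samples (40 repeats of 5
folds).  Methods are compared by the rank-sum of their median training
and test concordance; the winner's most frequently selected features,
truncated to its median per-run selection count, form the final set.

No information from a test fold ever reaches a selection decision or a
scaling parameter: feature standardization uses training-fold statistics
only, and every selector sees training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coxsuite import (
    CLINICAL_COVARIATES,
    ConvergenceError,
    CoxError,
    cox_fit,
    harrell_c,
    lr_compare,
    prepare_design,
)

__all__ = [
    "CVPartition",
    "SelectionRunResult",
    "SelectionSummary",
    "volume_filter",
    "redundancy_filter",
    "event_matched_folds",
    "select_univariable",
    "select_multivariable_lr",
    "select_mrmr",
    "run_selection_comparison",
    "METHODS",
]

METHODS = ("univariable", "multivariable", "mrmr")


# ---------------------------------------------------------------------------
# unsupervised screens


def volume_filter(
    features: pd.DataFrame,
    tumour_volume,
    rho_threshold: float = 0.5,
) -> list[str]:
    """Drop features confounded with tumour volume.

    A feature is removed when |Spearman rho(feature, volume)| exceeds the
    threshold; constant features (rho undefined) are retained with a
    warning.
    """
    vol = np.asarray(tumour_volume, dtype=float)
    if np.any(vol <= 0):
        raise ValueError("tumour volumes must be positive")
    kept = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.all(x == x[0]):
            warnings.warn(f"constant feature {name!r}: volume correlation "
                          "undefined, retained", stacklevel=2)
            kept.append(name)
            continue
        rho = stats.spearmanr(x, vol).statistic
        if not np.isfinite(rho) or abs(rho) <= rho_threshold:
            kept.append(name)
    return kept


def redundancy_filter(features: pd.DataFrame, r_threshold: float = 0.5) -> list[str]:
    """Iteratively resolve redundant (|Pearson r| >= threshold) pairs.

    At each step the most correlated remaining pair is examined (ties by
    feature name) and its member with the larger mean |r| to all
    remaining features is removed (ties remove the lexicographically
    later name); repeats until no pair reaches the threshold.
    """
    cols = list(features.columns)
    if len(cols) < 2:
        return cols
    X = features.to_numpy(dtype=float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 0.0)
    alive = list(range(len(cols)))
    while True:
        sub = np.abs(R[np.ix_(alive, alive)])
        if sub.size == 0 or sub.max() < r_threshold - 1e-15:
            break
        # most correlated pair; ties resolved by (name_i, name_j)
        best = None
        m = sub.max()
        for ai in range(len(alive)):
            for aj in range(ai + 1, len(alive)):
                if sub[ai, aj] >= m - 1e-15:
                    pair = tuple(sorted((cols[alive[ai]], cols[alive[aj]])))
                    if best is None or pair < best[0]:
                        best = (pair, alive[ai], alive[aj])
        _, i, j = best
        others = [a for a in alive]
        mean_i = np.abs(R[i, [a for a in others if a != i]]).mean()
        mean_j = np.abs(R[j, [a for a in others if a != j]]).mean()
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j, key=lambda a: cols[a])
        alive.remove(drop)
        if len(alive) < 2:
            break
    del sd
    return [cols[a] for a in alive]


# ---------------------------------------------------------------------------
# event-matched stratified CV


@dataclass
class CVPartition:
    """One (train, test) split of one fold of one repeat."""

    run: int
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray


def event_matched_folds(event, k: int = 5, repeats: int = 40,
                        seed: int | np.random.Generator = 0) -> list[CVPartition]:
    """Stratified k-fold partitions balancing event counts across folds.

    Events are shuffled and dealt round-robin to folds, censored subjects
    likewise, so per-fold event counts differ by at most one.  ``repeats``
    independent partitions give ``repeats * k`` (train, test) pairs.
    """
    event = np.asarray(event).astype(int)
    n = len(event)
    ev_idx = np.where(event == 1)[0]
    ce_idx = np.where(event == 0)[0]
    if len(ev_idx) < k or len(ce_idx) < k:
        raise ValueError(f"need at least {k} events and {k} censored subjects")
    rng = np.random.default_rng(seed)
    parts = []
    for r in range(1, repeats + 1):
        folds: list[list[int]] = [[] for _ in range(k)]
        for pool in (ev_idx, ce_idx):
            sh = rng.permutation(pool)
            for i, idx in enumerate(sh):
                folds[i % k].append(int(idx))
        for f in range(k):
            test = np.sort(np.asarray(folds[f], dtype=int))
            train = np.sort(np.asarray(
                [i for g in range(k) if g != f for i in folds[g]], dtype=int))
            parts.append(CVPartition(run=r, fold=f + 1, train_idx=train,
                                     test_idx=test))
    return parts


# ---------------------------------------------------------------------------
# supervised selectors (training data only)


def _univariable_stats(features: pd.DataFrame, time, event) -> pd.DataFrame:
    """Per-feature univariable Cox coefficient, z and Wald p; features
    whose fit fails are recorded with NaN."""
    rows = {}
    for name in features.columns:
        x = features[[name]].to_numpy()
        try:
            fit = cox_fit(x, time, event, names=[name])
            rows[name] = {"coef": fit.coef[0], "z": fit.wald_z[0],
                          "p": fit.wald_p[0]}
        except (CoxError, ConvergenceError) as exc:
            warnings.warn(f"univariable fit failed for {name!r}: {exc}",
                          stacklevel=2)
            rows[name] = {"coef": np.nan, "z": np.nan, "p": np.nan}
    return pd.DataFrame.from_dict(rows, orient="index")


def select_univariable(features: pd.DataFrame, time, event,
                       alpha: float = 0.05) -> list[str]:
    """Features univariably associated with outcome (Cox Wald p < alpha)."""
    st = _univariable_stats(features, time, event)
    return [n for n in features.columns if np.isfinite(st.loc[n, "p"])
            and st.loc[n, "p"] < alpha]


def select_multivariable_lr(features: pd.DataFrame, clinical: pd.DataFrame,
                            time, event, alpha: float = 0.05) -> list[str]:
    """Features that significantly improve the clinical Cox model in a
    1-df likelihood-ratio test."""
    base = cox_fit(clinical, time, event, names=list(clinical.columns))
    kept = []
    for name in features.columns:
        D = pd.concat([clinical.reset_index(drop=True),
                       features[[name]].reset_index(drop=True)], axis=1)
        try:
            ext = cox_fit(D, time, event, names=list(D.columns))
        except (CoxError, ConvergenceError) as exc:
            warnings.warn(f"clinical+{name!r} fit failed: {exc}", stacklevel=2)
            continue
        if lr_compare(base, ext).p_value < alpha:
            kept.append(name)
    return kept


def select_mrmr(features: pd.DataFrame, time, event, max_k: int = 10,
                relevance: pd.Series | None = None) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance ranking for survival.

    Relevance is the absolute univariable Cox Wald z; redundancy is the
    mean |Pearson r| to already-selected features; the greedy score is
    relevance − redundancy, stopping when the best remaining score is
    <= 0 (no positive contribution) or ``max_k`` is reached.
    """
    if features.shape[1] == 0:
        return []
    if relevance is None:
        relevance = _univariable_stats(features, time, event)["z"].abs()
    rel = relevance.reindex(features.columns)
    cand = [n for n in features.columns if np.isfinite(rel[n])]
    if not cand:
        return []
    X = features[cand].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.abs(np.nan_to_num(np.corrcoef(X, rowvar=False), nan=0.0))
    if R.ndim == 0:
        R = np.ones((1, 1))
    idx = {n: i for i, n in enumerate(cand)}
    selected: list[str] = []
    while len(selected) < max_k:
        best_name, best_score = None, 0.0
        for n in cand:
            if n in selected:
                continue
            red = np.mean([R[idx[n], idx[s]] for s in selected]) if selected else 0.0
            score = float(rel[n]) - red
            if score > best_score or (
                score == best_score and best_name is not None and n < best_name
            ):
                best_name, best_score = n, score
        if best_name is None or best_score <= 0:
            break
        selected.append(best_name)
    return selected


# ---------------------------------------------------------------------------
# the 200-sample comparison


@dataclass
class SelectionRunResult:
    method: str
    run: int
    fold: int
    selected: list[str]
    c_train: float
    c_test: float
    failed: bool = False


@dataclass
class SelectionSummary:
    frequencies: dict[str, pd.Series]       # per method, % of runs (0..100)
    median_counts: dict[str, float]
    c_train_median: dict[str, float]
    c_test_median: dict[str, float]
    c_train_ci: dict[str, tuple[float, float]]
    c_test_ci: dict[str, tuple[float, float]]
    n_failed: dict[str, int]
    chosen_method: str = ""
    final_features: list[str] = field(default_factory=list)


def _scale_train_test(F_train: pd.DataFrame, F_test: pd.DataFrame):
    mu = F_train.mean()
    sd = F_train.std(ddof=0).replace(0.0, 1.0)
    return (F_train - mu) / sd, (F_test - mu) / sd


def run_single(
    method: str,
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    time,
    event,
    part: CVPartition,
    alpha: float = 0.05,
    mrmr_max_k: int = 10,
) -> SelectionRunResult:
    """One selection + model-fit + scoring pass for one partition.

    Scaling statistics and every selection decision are computed on the
    training rows only; the fitted clinical+selected model is then scored
    on both folds by Harrell's C of its linear predictor.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    tr, te = part.train_idx, part.test_idx
    F_tr, F_te = _scale_train_test(features.iloc[tr], features.iloc[te])
    C_tr = clinical.iloc[tr].reset_index(drop=True)
    C_te = clinical.iloc[te].reset_index(drop=True)
    F_tr = F_tr.reset_index(drop=True)
    F_te = F_te.reset_index(drop=True)
    t_tr, e_tr = time[tr], event[tr]
    t_te, e_te = time[te], event[te]
    try:
        if method == "univariable":
            sel = select_univariable(F_tr, t_tr, e_tr, alpha=alpha)
        elif method == "multivariable":
            sel = select_multivariable_lr(F_tr, C_tr, t_tr, e_tr, alpha=alpha)
        elif method == "mrmr":
            sel = select_mrmr(F_tr, t_tr, e_tr, max_k=mrmr_max_k)
        else:
            raise ValueError(f"unknown method {method!r}")
        D_tr = pd.concat([C_tr, F_tr[sel]], axis=1)
        D_te = pd.concat([C_te, F_te[sel]], axis=1)
        fit = cox_fit(D_tr, t_tr, e_tr, names=list(D_tr.columns))
        c_tr = harrell_c(fit.predict_risk(D_tr), t_tr, e_tr)
        c_te = harrell_c(fit.predict_risk(D_te), t_te, e_te)
        return SelectionRunResult(method, part.run, part.fold, sel, c_tr, c_te)
    except (CoxError, ConvergenceError, ValueError) as exc:
        warnings.warn(
            f"{method} run {part.run} fold {part.fold} failed: {exc}",
            stacklevel=2,
        )
        return SelectionRunResult(method, part.run, part.fold, [],
                                  np.nan, np.nan, failed=True)


def run_selection_comparison(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    partitions: list[CVPartition],
    methods=METHODS,
    alpha: float = 0.05,
    mrmr_max_k: int = 10,
) -> tuple[list[SelectionRunResult], SelectionSummary]:
    """Compare the selectors over all partitions and build the summary.

    ``cohort`` supplies the clinical covariates and outcome.  Methods are
    ranked by the sum of ranks of their median train and test C (lower
    wins; tie broken by higher median test C); the final feature set is
    the winner's features by descending selection frequency (ties by
    name), truncated to the winner's median selected-count.
    """
    clinical = prepare_design(cohort).reset_index(drop=True)
    time = cohort["time_months"].to_numpy(float)
    event = cohort["event"].to_numpy(int)
    features = features.reset_index(drop=True)

    results: list[SelectionRunResult] = []
    for method in methods:
        for part in partitions:
            results.append(
                run_single(method, features, clinical, time, event, part,
                           alpha=alpha, mrmr_max_k=mrmr_max_k)
            )

    n_runs = len(partitions)
    freqs, med_counts = {}, {}
    ctr_med, cte_med, ctr_ci, cte_ci, nfail = {}, {}, {}, {}, {}
    for method in methods:
        rs = [r for r in results if r.method == method]
        ok = [r for r in rs if not r.failed]
        nfail[method] = len(rs) - len(ok)
        counts = pd.Series(0.0, index=features.columns)
        for r in ok:
            for f in r.selected:
                counts[f] += 1
        freqs[method] = 100.0 * counts / n_runs
        med_counts[method] = float(np.median([len(r.selected) for r in ok])) \
            if ok else 0.0
        ctr = np.array([r.c_train for r in ok])
        cte = np.array([r.c_test for r in ok])
        ctr_med[method] = float(np.median(ctr)) if len(ctr) else np.nan
        cte_med[method] = float(np.median(cte)) if len(cte) else np.nan
        ctr_ci[method] = tuple(np.percentile(ctr, [2.5, 97.5])) if len(ctr) \
            else (np.nan, np.nan)
        cte_ci[method] = tuple(np.percentile(cte, [2.5, 97.5])) if len(cte) \
            else (np.nan, np.nan)

    # rank-sum over median train and test C (rank 1 = best = highest median)
    def ranks(vals: dict[str, float]) -> dict[str, float]:
        order = sorted(vals, key=lambda m: (-vals[m], m))
        r = {}
        for i, m in enumerate(order):
            r[m] = i + 1.0
        return r

    rtr, rte = ranks(ctr_med), ranks(cte_med)
    chosen = min(methods,
                 key=lambda m: (rtr[m] + rte[m], -cte_med[m] if
                                np.isfinite(cte_med[m]) else 0.0, m))
    k_final = int(round(med_counts[chosen]))
    order = sorted(features.columns, key=lambda f: (-freqs[chosen][f], f))
    final = [f for f in order if freqs[chosen][f] > 0][:k_final]
    summary = SelectionSummary(
        frequencies=freqs,
        median_counts=med_counts,
        c_train_median=ctr_med,
        c_test_median=cte_med,
        c_train_ci=ctr_ci,
        c_test_ci=cte_ci,
        n_failed=nfail,
        chosen_method=chosen,
        final_features=final,
    )
    return results, summary
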