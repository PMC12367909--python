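"""Unsupervised screens, event-matched CV, and the selector comparison."""

import numpy as np
import pandas as pd
import pytest

from radsurv.cvselect import (
    event_matched_folds,
    redundancy_filter,
    run_selection_comparison,
    run_single,
    select_mrmr,
    select_multivariable_lr,
    select_univariable,
    volume_filter,
)
from radsurv.coxsuite import prepare_design
from conftest import random_survival


# ---------------------------------------------------------------------------
# volume filter


def test_volume_filter_removes_volume_itself(rng):
    vol = rng.uniform(1, 50, 200)
    F = pd.DataFrame({"self": vol, "indep": rng.standard_normal(200)})
    kept = volume_filter(F, vol)
    assert kept == ["indep"]


def test_volume_filter_threshold_one_keeps_all(rng):
    vol = rng.uniform(1, 50, 100)
    F = pd.DataFrame({"a": vol, "b": vol**2})
    assert volume_filter(F, vol, rho_threshold=1.0) == ["a", "b"]


def test_volume_filter_constant_feature_warns_and_keeps(rng):
    vol = rng.uniform(1, 50, 60)
    F = pd.DataFrame({"flat": np.full(60, 3.0)})
    with pytest.warns(UserWarning, match="constant"):
        assert volume_filter(F, vol) == ["flat"]
    with pytest.raises(ValueError, match="positive"):
        volume_filter(F, np.zeros(60))


# ---------------------------------------------------------------------------
# redundancy filter


def test_redundancy_filter_drops_hub_feature(rng):
    """A correlates strongly with both B and C, so it has the largest
    mean |r| and is removed; B and C then fall below the threshold and
    both survive."""
    # exact sample correlations: orthonormalize, then apply the Cholesky
    # factor of the target correlation matrix
    n = 500
    # (0.9, 0.6, 0.1) is not a positive-definite correlation triple;
    # (0.85, 0.6, 0.2) is, and exercises the same removal logic
    target = np.array([[1.0, 0.85, 0.6], [0.85, 1.0, 0.2], [0.6, 0.2, 1.0]])
    E = rng.standard_normal((n, 3))
    E = E - E.mean(axis=0)
    Q, _ = np.linalg.qr(E)
    X = Q @ np.linalg.cholesky(target).T
    F = pd.DataFrame(X, columns=["A", "B", "C"])
    R = F.corr().abs()
    np.testing.assert_allclose(R.to_numpy(), np.abs(target), atol=1e-10)
    kept = redundancy_filter(F, r_threshold=0.5)
    assert "A" not in kept and set(kept) == {"B", "C"}


def test_redundancy_filter_orthogonal_features_survive(rng):
    F = pd.DataFrame(rng.standard_normal((500, 5)),
                     columns=list("abcde"))
    assert set(redundancy_filter(F)) == set("abcde")


def test_redundancy_filter_duplicated_columns(rng):
    x = rng.standard_normal(100)
    y = rng.standard_normal(100)
    F = pd.DataFrame({"x1": x, "x2": x, "y1": y, "y2": y})
    kept = redundancy_filter(F)
    assert len([k for k in kept if k.startswith("x")]) == 1
    assert len([k for k in kept if k.startswith("y")]) == 1


# ---------------------------------------------------------------------------
# folds


def test_event_matched_folds_exact_balance():
    event = np.r_[np.ones(60, int), np.zeros(118, int)]
    parts = event_matched_folds(event, k=5, repeats=1, seed=0)
    assert len(parts) == 5
    for p in parts:
        assert event[p.test_idx].sum() == 12
        # folds partition the cohort
        assert len(np.intersect1d(p.train_idx, p.test_idx)) == 0
        assert len(p.train_idx) + len(p.test_idx) == len(event)


def test_event_matched_folds_near_balance():
    event = np.r_[np.ones(61, int), np.zeros(110, int)]
    parts = event_matched_folds(event, k=5, repeats=2, seed=3)
    assert len(parts) == 10
    for p in parts:
        assert event[p.test_idx].sum() in (12, 13)


def test_event_matched_folds_deterministic_and_validated():
    event = np.r_[np.ones(20, int), np.zeros(40, int)]
    a = event_matched_folds(event, repeats=3, seed=7)
    b = event_matched_folds(event, repeats=3, seed=7)
    for pa, pb in zip(a, b):
        np.testing.assert_array_equal(pa.test_idx, pb.test_idx)
    with pytest.raises(ValueError, match="at least"):
        event_matched_folds(np.r_[np.ones(3, int), np.zeros(30, int)], k=5)


# ---------------------------------------------------------------------------
# selectors


def _informative_setup(seed=0, n=150):
    rng = np.random.default_rng(seed)
    X, time, event = random_survival(rng, n=n, beta=[1.2, 0.0, 0.0])
    F = pd.DataFrame(X, columns=["signal", "noise1", "noise2"])
    return F, time, event


def test_select_univariable_signal_and_alpha_zero():
    F, time, event = _informative_setup()
    sel = select_univariable(F, time, event, alpha=0.05)
    assert "signal" in sel
    assert select_univariable(F, time, event, alpha=0.0) == []


def test_select_univariable_type_one_error_calibrated():
    hits = 0
    runs = 120
    for s in range(runs):
        rng = np.random.default_rng(5000 + s)
        X, t, e = random_survival(rng, n=100, p=1)
        hits += len(select_univariable(pd.DataFrame(X, columns=["n0"]), t, e))
    rate = hits / runs
    assert 0.01 < rate < 0.11   # nominal 5%, binomial tolerance


def test_select_multivariable_duplicate_clinical_not_selected(small_table):
    clinical = prepare_design(small_table).reset_index(drop=True)
    time = small_table["time_months"].to_numpy()
    event = small_table["event"].to_numpy()
    F = pd.DataFrame({"dup_age": clinical["age"] + 1e-9})
    sel = select_multivariable_lr(F, clinical, time, event, alpha=0.05)
    assert "dup_age" not in sel


def test_select_multivariable_alpha_one_selects_all_convergent():
    F, time, event = _informative_setup()
    clinical = pd.DataFrame({"c": np.random.default_rng(0).standard_normal(len(F))})
    sel = select_multivariable_lr(F, clinical, time, event, alpha=1.0)
    assert set(sel) == set(F.columns)


def test_select_mrmr_single_candidate_and_duplicates():
    F, time, event = _informative_setup()
    only = select_mrmr(F[["signal"]], time, event)
    assert only == ["signal"]
    # duplicated informative feature: second copy has redundancy 1
    F2 = pd.DataFrame({"s1": F["signal"], "s2": F["signal"]})
    sel = select_mrmr(F2, time, event)
    rel = abs(float(select_relevance(F2, time, event)["s2"]))
    if rel > 1:
        assert set(sel) == {"s1", "s2"}
    else:
        assert len(sel) == 1


def select_relevance(F, time, event):
    from radsurv.cvselect import _univariable_stats

    return _univariable_stats(F, time, event)["z"].abs()


def test_select_mrmr_redundant_noise_terminates_early():
    """Once redundancy (mean |r| to picked features) exceeds the noise
    features' spurious |z| relevance, the greedy score goes non-positive
    and selection stops before max_k."""
    for s in range(20):
        rng = np.random.default_rng(900 + s)
        X, t, e = random_survival(rng, n=80, p=2)
        base = X[:, 0]
        # six near-duplicates of one noise feature: redundancy ~1 after pick 1
        F = pd.DataFrame({f"d{i}": base + 0.05 * rng.standard_normal(len(base))
                          for i in range(6)})
        sel = select_mrmr(F, t, e, max_k=6)
        rel = select_relevance(F, t, e)
        red = F.corr().abs().to_numpy()
        np.fill_diagonal(red, np.nan)
        min_red = np.nanmin(red)
        if (rel < min_red).iloc[1:].all():
            # every later pick would score relevance − redundancy <= 0
            assert len(sel) == 1
        assert len(sel) <= 6


# ---------------------------------------------------------------------------
# comparison bookkeeping


def _make_cohort_frame(rng, n=120, signal=1.0):
    X, time, event = random_survival(rng, n=n, beta=[signal, 0, 0, 0])
    F = pd.DataFrame(X, columns=["planted", "n1", "n2", "n3"])
    tab = pd.DataFrame(
        {
            "age": rng.normal(70, 5, n),
            "psa": rng.lognormal(3, 0.8, n),
            "isup": rng.integers(1, 6, n),
            "tstage": rng.choice(["T2", "T3"], n),
            "treatment": rng.choice(["EBRT", "HDR+EBRT"], n),
            "tumour_volume_ml": rng.lognormal(1.6, 1.0, n),
            "ragnum32": rng.normal(0.3, 0.2, n),
            "west28": rng.normal(1.4, 1.0, n),
            "time_months": time,
            "event": event,
        }
    )
    return F, tab


def test_comparison_bookkeeping_and_planted_feature_found(rng):
    F, tab = _make_cohort_frame(rng, n=140, signal=1.2)
    parts = event_matched_folds(tab["event"], k=5, repeats=8, seed=1)
    results, summary = run_selection_comparison(F, tab, parts)
    assert len(results) == 3 * 40
    for m in ("univariable", "multivariable", "mrmr"):
        assert len([r for r in results if r.method == m]) == 40
        assert (summary.frequencies[m] >= 0).all()
        assert (summary.frequencies[m] <= 100).all()
    # the planted predictor tops the winning method's stability ranking
    top = summary.frequencies[summary.chosen_method].idxmax()
    assert top == "planted"
    assert "planted" in summary.final_features
    assert len(summary.final_features) == int(round(
        summary.median_counts[summary.chosen_method]))


def test_comparison_zero_candidates_ties_methods(rng):
    F, tab = _make_cohort_frame(rng, n=100, signal=0.0)
    parts = event_matched_folds(tab["event"], k=5, repeats=2, seed=2)
    results, summary = run_selection_comparison(F.iloc[:, :0], tab, parts)
    # all models collapse to clinical-only: identical medians per method
    meds = set(round(v, 12) for v in summary.c_test_median.values())
    assert len(meds) == 1
    assert summary.final_features == []
    assert summary.chosen_method  # tie-break still names a winner


def test_run_single_uses_training_rows_only(rng):
    """Scaling parameters come from the training fold: a feature shifted
    on the test fold only does not change the selection outcome."""
    F, tab = _make_cohort_frame(rng, n=100, signal=1.0)
    clinical = prepare_design(tab).reset_index(drop=True)
    parts = event_matched_folds(tab["event"], k=5, repeats=1, seed=3)
    p = parts[0]
    r1 = run_single("univariable", F, clinical, tab["time_months"],
                    tab["event"], p)
    F_shift = F.copy()
    F_shift.iloc[p.test_idx] += 100.0
    r2 = run_single("univariable", F_shift, clinical, tab["time_months"],
                    tab["event"], p)
    assert r1.selected == r2.selected
    assert r1.c_train == r2.c_train
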