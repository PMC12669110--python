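"""Feature assembly, RFE, RF training, evaluation, classifier comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.datasets import make_blobs
from sklearn.metrics import roc_auc_score

from octcvd.classify import (
    DEFAULT_K,
    DEFAULT_K_BY_MODE,
    MODES,
    FeatureMatrix,
    HeldoutRegistry,
    assemble_features,
    auroc,
    bootstrap_auroc_se,
    compare_classifiers,
    encode_metadata,
    evaluate,
    latent_names,
    rfe_select,
    split_523,
    train_rf,
)
from octcvd.errors import ConfigurationError


def _metadata(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sex": rng.choice(["F", "M"], n),
            "age": rng.normal(60, 6, n),
            "hba1c": rng.normal(36.5, 5, n),
            "sbp": rng.normal(146, 19, n),
            "dbp": rng.normal(84, 10, n),
            "alcohol": rng.choice(["never", "previous", "current", "NA"], n),
            "bmi": rng.normal(28, 4.4, n),
            "ethnicity": rng.choice(["White", "Mixed", "Asian"], n),
            "cvd_label": rng.choice(["CVD+", "CVD-"], n),
        },
        index=[f"S{i:03d}" for i in range(n)],
    )


def _latents(n, D, eye, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((n, D)),
        index=[f"S{i:03d}" for i in range(n)],
        columns=latent_names(eye, D),
    )


def test_metadata_mode_has_exactly_eight_columns():
    fm = assemble_features(None, None, _metadata(20), "MTDT")
    assert fm.X.shape[1] == 8
    assert list(fm.X.columns) == [
        "sex", "age", "hba1c", "sbp", "dbp", "alcohol", "bmi", "ethnicity",
    ]


def test_both_eyes_with_metadata_has_264_columns():
    meta = _metadata(15)
    fm = assemble_features(_latents(15, 128, "L"), _latents(15, 128, "R"), meta,
                           "BE-MTDT")
    assert fm.X.shape[1] == 128 + 128 + 8
    # fixed concatenation order: [zl | zr | metadata]
    assert fm.columns[0] == "zl000"
    assert fm.columns[128] == "zr000"
    assert fm.columns[256] == "sex"


def test_left_eye_mode_is_projection_of_both_eyes():
    meta = _metadata(12)
    zl, zr = _latents(12, 16, "L", 1), _latents(12, 16, "R", 2)
    le = assemble_features(zl, zr, meta, "LE")
    be = assemble_features(zl, zr, meta, "BE")
    pd.testing.assert_frame_equal(le.X, be.X[le.columns])


def test_missing_subject_error_names_subjects():
    meta = _metadata(10)
    zl = _latents(10, 8, "L").drop(index=["S003"])
    with pytest.raises(ConfigurationError, match="S003"):
        assemble_features(zl, _latents(10, 8, "R"), meta, "LE")


def test_unknown_mode_rejected():
    with pytest.raises(ConfigurationError):
        assemble_features(None, None, _metadata(5), "XYZ")


def test_metadata_encoding_is_numeric_and_complete():
    meta = _metadata(30, seed=5)
    meta.loc[meta.index[0], "bmi"] = np.nan
    enc = encode_metadata(meta)
    assert not enc.isna().any().any()
    assert enc.loc[meta.index[0], "bmi"] == 0.0  # gap represented as 0
    assert set(enc["sex"].unique()) <= {0.0, 1.0}


def test_default_feature_counts_follow_channel_mode():
    assert DEFAULT_K == 10
    assert DEFAULT_K_BY_MODE == {"RE": 5}


def test_rfe_identity_when_k_equals_columns():
    meta = _metadata(20)
    fm = assemble_features(None, None, meta, "MTDT")
    assert rfe_select(fm, k=8) == list(fm.X.columns)


def test_rfe_rejects_bad_k():
    fm = assemble_features(None, None, _metadata(10), "MTDT")
    with pytest.raises(ConfigurationError):
        rfe_select(fm, k=0)
    with pytest.raises(ConfigurationError):
        rfe_select(fm, k=99)


def test_rfe_recovers_planted_informative_column():
    """One informative column among 20 noise columns survives selection to
    k = 5 in at least 95% of seeded runs."""
    hits = 0
    n_runs = 100
    for seed in range(n_runs):
        rng = np.random.default_rng(1000 + seed)
        n = 500
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 21))
        X[:, 7] += 1.5 * y  # planted signal
        fm = FeatureMatrix(
            "MTDT",
            pd.DataFrame(X, columns=[f"c{i:02d}" for i in range(21)]),
            pd.Series(y),
        )
        cols = rfe_select(fm, k=5, seed=seed, step=0.25, n_estimators=30)
        hits += "c07" in cols
    assert hits >= 95


def test_grid_of_size_one_is_chosen():
    meta = _metadata(40, seed=3)
    fm = assemble_features(None, None, meta, "MTDT")
    grid = {"n_estimators": [37]}
    clf, best = train_rf(fm, grid=grid, seed=0)
    assert best == {"n_estimators": 37}
    assert clf.n_estimators == 37


def test_single_class_input_raises():
    meta = _metadata(10)
    meta["cvd_label"] = "CVD-"
    fm = assemble_features(None, None, meta, "MTDT")
    with pytest.raises(ConfigurationError):
        train_rf(fm)


def test_separable_blobs_reach_high_auroc():
    X, y = make_blobs(
        n_samples=200, centers=2, cluster_std=1.0, center_box=(-8, 8),
        random_state=4,
    )
    fm = FeatureMatrix(
        "MTDT", pd.DataFrame(X, columns=["a", "b"]), pd.Series(y)
    )
    clf, _ = train_rf(fm, grid={"n_estimators": [100]}, seed=0)
    probs = clf.predict_proba(X)[:, 1]
    assert auroc(y, probs) > 0.95


def test_split_523_proportions_and_stratification():
    meta = _metadata(200, seed=9)
    labels = (meta["cvd_label"] == "CVD+").astype(int)
    tr, va, te = split_523(meta.index, labels, seed=0)
    n = len(meta)
    assert len(tr) / n == pytest.approx(0.5, abs=0.02)
    assert len(va) / n == pytest.approx(0.2, abs=0.02)
    assert len(te) / n == pytest.approx(0.3, abs=0.02)
    assert set(tr) | set(va) | set(te) == set(meta.index)
    assert not (set(tr) & set(te)) and not (set(va) & set(te))


def test_perfect_classifier_metrics_are_all_one():
    labels = np.array([1, 1, 0, 0, 1])
    probs = labels.astype(float)
    rep = evaluate(probs, labels, n_boot=0)
    assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0
    assert rep.auroc == 1.0
    assert (rep.tp, rep.tn, rep.fp, rep.fn) == (3, 2, 0, 0)


def test_four_sample_confusion_and_pairwise_auroc():
    """Labels (+,+,-,-) with probabilities (0.9, 0.4, 0.6, 0.1) at t=0.5:
    confusion counts all equal 1; AUROC = 3/4 by enumerating all 4
    positive-negative pairs."""
    labels = np.array([1, 1, 0, 0])
    probs = np.array([0.9, 0.4, 0.6, 0.1])
    rep = evaluate(probs, labels, t=0.5, n_boot=0)
    assert (rep.tp, rep.fn, rep.fp, rep.tn) == (1, 1, 1, 1)
    wins = 0.0
    for p in probs[labels == 1]:
        for q in probs[labels == 0]:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    assert rep.auroc == pytest.approx(wins / 4) == pytest.approx(0.75)


def test_metric_identities_by_brute_force_counting():
    rng = np.random.default_rng(12)
    labels = rng.integers(0, 2, 60)
    probs = rng.random(60)
    rep = evaluate(probs, labels, n_boot=0)
    assert rep.tp + rep.tn + rep.fp + rep.fn == rep.n_test == 60
    assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))
    assert rep.specificity == pytest.approx(rep.tn / (rep.tn + rep.fp))
    assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / 60)


def test_rank_auroc_agrees_with_reference_implementation():
    rng = np.random.default_rng(13)
    labels = rng.integers(0, 2, 200)
    probs = np.round(rng.random(200), 2)  # force ties
    assert auroc(labels, probs) == pytest.approx(roc_auc_score(labels, probs))


def test_bootstrap_ci_width_shrinks_with_test_size():
    rng = np.random.default_rng(14)

    def ci_width(n):
        labels = rng.integers(0, 2, n)
        probs = np.clip(0.5 + 0.3 * (labels - 0.5) + rng.normal(0, 0.25, n), 0, 1)
        rep = evaluate(probs, labels, n_boot=400, seed=0)
        lo, hi = rep.ci["auroc"]
        return hi - lo

    assert ci_width(400) < ci_width(100)


def test_identical_classifiers_give_zero_chi2_p_one():
    labels = np.array([1, 0, 1, 0, 1])
    pred = np.array([1, 0, 0, 0, 1])
    chi2, df, p = compare_classifiers(pred, pred, labels)
    assert (chi2, df, p) == (0.0, 1, 1.0)


def test_mcnemar_closed_form_without_continuity_correction():
    """Discordant counts b=10, c=0 give chi2 = (10-0)^2/10 = 10, df = 1."""
    labels = np.zeros(30, dtype=int)
    pred_a = np.zeros(30, dtype=int)  # all correct
    pred_b = np.zeros(30, dtype=int)
    pred_b[:10] = 1  # b wrong where a is right: b=10, c=0
    chi2, df, p = compare_classifiers(pred_a, pred_b, labels)
    assert chi2 == pytest.approx(10.0)
    assert df == 1
    assert p == pytest.approx(stats.chi2.sf(10.0, 1))


def test_mcnemar_agrees_with_statsmodels():
    sm = pytest.importorskip("statsmodels.stats.contingency_tables")
    rng = np.random.default_rng(15)
    labels = rng.integers(0, 2, 120)
    pred_a = np.where(rng.random(120) < 0.8, labels, 1 - labels)
    pred_b = np.where(rng.random(120) < 0.7, labels, 1 - labels)
    chi2, df, p = compare_classifiers(pred_a, pred_b, labels)
    ca, cb = pred_a == labels, pred_b == labels
    table = [
        [np.sum(ca & cb), np.sum(ca & ~cb)],
        [np.sum(~ca & cb), np.sum(~ca & ~cb)],
    ]
    ref = sm.mcnemar(table, exact=False, correction=False)
    assert chi2 == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
    assert df == 1


def test_comparison_requires_matching_lengths():
    with pytest.raises(ConfigurationError):
        compare_classifiers([1, 0], [1], [1, 0])


def test_contingency_method_available():
    rng = np.random.default_rng(16)
    labels = rng.integers(0, 2, 80)
    pred_a = rng.integers(0, 2, 80)
    pred_b = rng.integers(0, 2, 80)
    chi2, df, p = compare_classifiers(pred_a, pred_b, labels, method="contingency")
    assert df == 1 and 0 <= p <= 1


def test_test_set_registry_detects_change():
    reg = HeldoutRegistry(["a", "b", "c"])
    reg.assert_unchanged(["c", "b", "a"])  # order-insensitive
    with pytest.raises(ConfigurationError):
        reg.assert_unchanged(["a", "b"])


def test_bootstrap_auroc_se_positive():
    rng = np.random.default_rng(17)
    labels = rng.integers(0, 2, 100)
    probs = rng.random(100)
    assert bootstrap_auroc_se(probs, labels, n_boot=200, seed=0) > 0


def test_all_seven_modes_enumerated():
    assert MODES == ("LE", "RE", "BE", "MTDT", "LE-MTDT", "RE-MTDT", "BE-MTDT")
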