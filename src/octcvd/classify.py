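"""Multimodal random-forest classification over seven data-channel modes.

Feature channels are the left-eye latent block (``zl000``..), the right-eye
latent block (``zr000``..) and eight encoded clinical variables; the seven
modes are LE, RE, BE, MTDT, LE-MTDT, RE-MTDT and BE-MTDT. Features are
reduced by recursive feature elimination (top 10 by default, top 5 for the
RE mode), classifiers are tuned by seeded 5-fold grid search on AUROC, and
every model is evaluated on one fixed held-out test split at probability
threshold 0.5 with bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from octcvd.errors import ConfigurationError
from octcvd.utils import ids_hash

MODES = ("LE", "RE", "BE", "MTDT", "LE-MTDT", "RE-MTDT", "BE-MTDT")

#: the eight clinical variables used as metadata features
METADATA_FEATURES = ("sex", "age", "hba1c", "sbp", "dbp", "alcohol", "bmi", "ethnicity")

_SEX_CODE = {"F": 0.0, "M": 1.0}
_ALCOHOL_CODE = {"never": 0.0, "previous": 1.0, "current": 2.0, "NA": 0.0}
_ETHNICITY_CODE = {
    "White": 0.0, "Mixed": 1.0, "Asian": 2.0, "Black": 3.0,
    "Chinese": 4.0, "Other": 5.0,
}

DEFAULT_RF_GRID = {
    "n_estimators": [200, 400],
    "max_depth": [None, 8],
    "min_samples_leaf": [1, 3],
}

#: RFE keeps the top 10 features, except the right-eye-only mode (top 5)
DEFAULT_K = 10
DEFAULT_K_BY_MODE = {"RE": 5}


def latent_names(eye: str, D: int) -> List[str]:
    prefix = {"L": "zl", "R": "zr"}[eye]
    return [f"{prefix}{d:03d}" for d in range(D)]


def encode_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Encode the eight clinical variables as numeric columns.

    Categoricals get integer codes (random forests are invariant to any
    monotone coding); missing continuous values are imputed as 0, matching
    the gap-handling convention of the clinical comparator.
    """
    out = pd.DataFrame(index=metadata.index)
    out["sex"] = metadata["sex"].map(_SEX_CODE)
    out["age"] = metadata["age"].astype(float)
    out["hba1c"] = metadata["hba1c"].astype(float)
    out["sbp"] = metadata["sbp"].astype(float)
    out["dbp"] = metadata["dbp"].astype(float)
    out["alcohol"] = metadata["alcohol"].map(_ALCOHOL_CODE)
    out["bmi"] = metadata["bmi"].astype(float)
    out["ethnicity"] = metadata["ethnicity"].map(_ETHNICITY_CODE)
    return out.fillna(0.0)


@dataclass
class FeatureMatrix:
    mode: str
    X: pd.DataFrame  # rows: subjects (index = subject_id)
    y: pd.Series  # 1 = CVD+, 0 = CVD-

    @property
    def columns(self) -> List[str]:
        return list(self.X.columns)

    def restrict(self, columns: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.mode, self.X[list(columns)], self.y)

    def subset(self, subject_ids: Sequence[str]) -> "FeatureMatrix":
        ids = list(subject_ids)
        return FeatureMatrix(self.mode, self.X.loc[ids], self.y.loc[ids])


def assemble_features(
    latents_L: Optional[pd.DataFrame],
    latents_R: Optional[pd.DataFrame],
    metadata: pd.DataFrame,
    mode: str,
) -> FeatureMatrix:
    """Build the feature matrix for one channel mode.

    ``latents_L``/``latents_R`` are subject-indexed frames with columns
    ``zl000``../``zr000``..; ``metadata`` must carry the raw clinical
    columns plus ``cvd_label``. Columns are concatenated in the fixed order
    [zl | zr | metadata], restricted to the mode.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; expected one of {MODES}")
    subjects = metadata.index
    blocks: List[pd.DataFrame] = []
    if mode in ("LE", "BE", "LE-MTDT", "BE-MTDT"):
        _check_subjects(latents_L, subjects, "left-eye latents")
        blocks.append(latents_L.loc[subjects])
    if mode in ("RE", "BE", "RE-MTDT", "BE-MTDT"):
        _check_subjects(latents_R, subjects, "right-eye latents")
        blocks.append(latents_R.loc[subjects])
    if mode in ("MTDT", "LE-MTDT", "RE-MTDT", "BE-MTDT"):
        blocks.append(encode_metadata(metadata))
    X = pd.concat(blocks, axis=1)
    if X.isna().any().any():
        raise ConfigurationError("feature matrix contains missing values")
    y = (metadata["cvd_label"] == "CVD+").astype(int)
    return FeatureMatrix(mode=mode, X=X, y=y)


def _check_subjects(latents, subjects, what):
    if latents is None:
        raise ConfigurationError(f"{what} required but not provided")
    missing = [s for s in subjects if s not in latents.index]
    if missing:
        raise ConfigurationError(f"subjects missing from {what}: {missing}")


def split_523(
    subject_ids: Sequence[str], labels: pd.Series, seed: int
) -> Tuple[List[str], List[str], List[str]]:
    """Seeded, label-stratified ~5:2:3 train/validation/test subject split."""
    rng = np.random.default_rng(seed)
    ids = np.asarray(list(subject_ids))
    train, val, test = [], [], []
    for lab in np.unique(labels.loc[ids]):
        grp = ids[labels.loc[ids].values == lab]
        grp = grp[rng.permutation(len(grp))]
        n = len(grp)
        n_tr, n_va = int(round(0.5 * n)), int(round(0.2 * n))
        train += list(grp[:n_tr])
        val += list(grp[n_tr : n_tr + n_va])
        test += list(grp[n_tr + n_va :])
    return train, val, test


def rfe_select(
    fm: FeatureMatrix, k: int = DEFAULT_K, seed: int = 0, step: float = 0.1,
    n_estimators: int = 200,
) -> List[str]:
    """Recursive feature elimination with forest importances.

    Drops ``step`` (fraction) of the remaining columns per round until ``k``
    remain; returns the surviving column names ordered by final importance.
    """
    if k <= 0:
        raise ConfigurationError("k must be positive")
    if k > fm.X.shape[1]:
        raise ConfigurationError("k exceeds the number of columns")
    if k == fm.X.shape[1]:
        return list(fm.X.columns)
    est = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rfe = RFE(est, n_features_to_select=k, step=step)
    rfe.fit(fm.X.values, fm.y.values)
    chosen = np.asarray(fm.X.columns)[rfe.support_]
    final = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    final.fit(fm.X[chosen].values, fm.y.values)
    order = np.argsort(final.feature_importances_)[::-1]
    return [str(c) for c in chosen[order]]


def train_rf(
    fm: FeatureMatrix,
    grid: Optional[Dict[str, list]] = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> Tuple[RandomForestClassifier, Dict[str, object]]:
    """Seeded grid search (stratified K-fold, AUROC) refit on the full split."""
    if fm.y.nunique() < 2:
        raise ConfigurationError("training data must contain both classes")
    if grid is None:
        grid = DEFAULT_RF_GRID
    # folds cannot exceed the minority-class count on small cohorts
    n_splits = max(2, min(cv_folds, int(fm.y.value_counts().min())))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed),
        grid,
        scoring="roc_auc",
        cv=cv,
        n_jobs=1,
    )
    search.fit(fm.X.values, fm.y.values)
    return search.best_estimator_, dict(search.best_params_)


def auroc(labels: np.ndarray, probs: np.ndarray) -> float:
    """AUROC by the rank statistic; ties contribute one half.

    Equivalent to the probability that a random positive outscores a random
    negative (all-pairs comparison).
    """
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    ranks = stats.rankdata(probs)
    r_pos = ranks[labels == 1].sum()
    n1, n0 = len(pos), len(neg)
    return float((r_pos - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class EvalReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auroc: float
    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float
    n_test: int
    ci: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    auroc_se: float = float("nan")  # bootstrap SE over test subjects

    def to_dict(self) -> Dict[str, object]:
        d = {k: v for k, v in vars(self).items() if k != "ci"}
        for metric, (lo, hi) in self.ci.items():
            d[f"{metric}_ci_lo"], d[f"{metric}_ci_hi"] = lo, hi
        return d


def _threshold_metrics(labels, probs, t):
    pred = (probs >= t).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    acc = (tp + tn) / len(labels)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return acc, sens, spec, tp, tn, fp, fn


def evaluate(
    probs: np.ndarray,
    labels: np.ndarray,
    t: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Threshold metrics, AUROC and 95% bootstrap CIs on a test set.

    ``probs >= t`` predicts CVD+. CIs are percentile bootstrap over test
    subjects, seeded.
    """
    labels = np.asarray(labels).astype(int)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ConfigurationError("labels and probabilities differ in length")
    acc, sens, spec, tp, tn, fp, fn = _threshold_metrics(labels, probs, t)
    auc = auroc(labels, probs)

    ci = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(labels)
        boots = {"accuracy": [], "sensitivity": [], "specificity": [], "auroc": []}
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            lb, pb = labels[idx], probs[idx]
            if lb.min() == lb.max():
                continue  # degenerate resample: one class only
            a, se, sp, *_ = _threshold_metrics(lb, pb, t)
            boots["accuracy"].append(a)
            boots["sensitivity"].append(se)
            boots["specificity"].append(sp)
            boots["auroc"].append(auroc(lb, pb))
        for metric, vals in boots.items():
            if vals:
                lo, hi = np.percentile(vals, [2.5, 97.5])
                ci[metric] = (float(lo), float(hi))
        auroc_se = (
            float(np.std(boots["auroc"], ddof=1)) if boots["auroc"] else float("nan")
        )
    else:
        auroc_se = float("nan")
    return EvalReport(
        accuracy=acc, sensitivity=sens, specificity=spec, auroc=auc,
        tp=tp, tn=tn, fp=fp, fn=fn, threshold=t, n_test=len(labels), ci=ci,
        auroc_se=auroc_se,
    )


def bootstrap_auroc_se(
    probs: np.ndarray, labels: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> float:
    """Bootstrap standard error of the AUROC over test subjects."""
    labels = np.asarray(labels).astype(int)
    probs = np.asarray(probs, dtype=float)
    rng = np.random.default_rng(seed)
    vals = []
    n = len(labels)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if labels[idx].min() == labels[idx].max():
            continue
        vals.append(auroc(labels[idx], probs[idx]))
    return float(np.std(vals, ddof=1))


def compare_classifiers(
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    labels: np.ndarray,
    method: str = "mcnemar",
) -> Tuple[float, int, float]:
    """Paired comparison of two classifiers on the same test subjects.

    Default is McNemar's test without continuity correction on the 2x2
    table of discordant correctness: chi2 = (b - c)^2 / (b + c), df = 1.
    ``method="contingency"`` instead runs a Pearson chi-squared test on the
    full correct/incorrect contingency table.
    """
    pred_a = np.asarray(pred_a).astype(int)
    pred_b = np.asarray(pred_b).astype(int)
    labels = np.asarray(labels).astype(int)
    if not (len(pred_a) == len(pred_b) == len(labels)):
        raise ConfigurationError("prediction vectors differ in length")
    correct_a = pred_a == labels
    correct_b = pred_b == labels
    if method == "mcnemar":
        b = int(np.sum(correct_a & ~correct_b))
        c = int(np.sum(~correct_a & correct_b))
        if b + c == 0:
            return 0.0, 1, 1.0
        chi2 = (b - c) ** 2 / (b + c)
        return float(chi2), 1, float(stats.chi2.sf(chi2, 1))
    if method == "contingency":
        table = np.array(
            [
                [np.sum(correct_a), np.sum(~correct_a)],
                [np.sum(correct_b), np.sum(~correct_b)],
            ]
        )
        chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), int(df), float(p)
    raise ConfigurationError(f"unknown comparison method {method!r}")


class HeldoutRegistry:
    """Pins the held-out test split: the id hash is recorded once and every
    subsequent evaluation against the split must present the same ids."""

    def __init__(self, test_ids: Sequence[str]):
        self.test_hash = ids_hash(test_ids)

    def assert_unchanged(self, test_ids: Sequence[str]) -> None:
        if ids_hash(test_ids) != self.test_hash:
            raise ConfigurationError(
                "held-out test set changed between evaluations"
            )
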