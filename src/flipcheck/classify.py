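"""Random Forest flip classifiers and evaluation metrics.

One binary classifier is trained per residue class and flip type
(positive = peptide needs that flip, negative = correct tt−/cc−); the
per-flip classifiers of a residue class are combined into a single
multi-label verdict function.  Metrics are the Matthews correlation
coefficient (robust to the severe class imbalance of flip detection),
accuracy and the rank-statistic AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .config import RunConfig

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionTable",
    "TrainedClassifier",
    "confusion_table",
    "mcc",
    "accuracy",
    "auc",
    "cross_validate",
    "train_classifier",
    "combine_classifiers",
    "save_classifier",
    "load_classifier",
]

CORRECT_LABELS = ("tt-", "cc-")
_SS_CODE = {"H": 0.0, "E": 1.0, "C": 2.0}
_NON_FEATURES = ("label", "residue_class")


@dataclass
class ConfusionTable:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")


def confusion_table(truth, predicted, positive) -> ConfusionTable:
    """TP/FN/FP/TN counts for one binary task."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("label lists differ in length")
    tp = sum(1 for t, p in zip(truth, predicted) if t == positive and p == positive)
    fn = sum(1 for t, p in zip(truth, predicted) if t == positive and p != positive)
    fp = sum(1 for t, p in zip(truth, predicted) if t != positive and p == positive)
    tn = sum(1 for t, p in zip(truth, predicted) if t != positive and p != positive)
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)


def mcc(c: ConfusionTable) -> float:
    """Matthews correlation coefficient, in [−1, 1]."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        raise ValueError("MCC undefined: a margin is zero")
    return (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom)


def accuracy(c: ConfusionTable) -> float:
    if c.total == 0:
        raise ValueError("empty confusion table")
    return (c.tp + c.tn) / c.total


def auc(scores, labels, positive=1) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) statistic,
    ties averaged."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == positive else 0 for l in labels])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


# ---------------------------------------------------------------------------


def design_matrix(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric feature matrix from a feature table.

    Secondary-structure codes are ordinally encoded; inapplicable fields
    (Gly Cβ, no nearby helix, non-Xnpg WH score) become −1 so trees can
    branch on their absence.
    """
    df = df.drop(columns=[c for c in _NON_FEATURES if c in df.columns])
    df = df.copy()
    for col in ("ss1", "ss2", "ss3", "ss4"):
        if col in df.columns:
            df[col] = df[col].map(_SS_CODE).astype(float)
    df = df.astype(float).fillna(-1.0)
    return df.to_numpy(), list(df.columns)


@dataclass
class TrainedClassifier:
    residue_class: str
    flip_type: str
    model: RandomForestClassifier
    feature_names: list[str]
    resolution_max: float | None
    seed: int
    cv_summary: dict = field(default_factory=dict)

    def _matrix(self, df: pd.DataFrame) -> np.ndarray:
        x, names = design_matrix(df)
        if names != self.feature_names:
            raise ValueError("feature columns do not match the trained model")
        return x

    def predict_score(self, df: pd.DataFrame) -> np.ndarray:
        """Probability that the peptide needs this classifier's flip."""
        proba = self.model.predict_proba(self._matrix(df))
        pos = list(self.model.classes_).index(1)
        return proba[:, pos]

    def predict(self, df: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_score(df) >= threshold).astype(int)

    def feature_importances(self) -> pd.Series:
        return pd.Series(
            self.model.feature_importances_, index=self.feature_names
        ).sort_values(ascending=False)


def _task_frame(
    df: pd.DataFrame, residue_class: str, flip_type: str, cfg: RunConfig
) -> pd.DataFrame:
    """Rows for one binary task, with the class resolution window applied."""
    sel = df[df["residue_class"] == residue_class]
    sel = sel[sel["label"].isin([flip_type, *CORRECT_LABELS])]
    res_max = None
    if flip_type == "tt+":
        res_max = (
            cfg.resolution_max_gly_ttplus
            if residue_class == "X-Gly"
            else cfg.resolution_max_ttplus
        )
        sel = sel[sel["resolution"] <= res_max]
    return sel


def _balance(df: pd.DataFrame, y: np.ndarray, seed: int) -> pd.DataFrame:
    """Downsample the majority class to the minority count."""
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    n = min(len(idx_pos), len(idx_neg))
    keep = np.concatenate(
        [
            rng.choice(idx_pos, size=n, replace=False),
            rng.choice(idx_neg, size=n, replace=False),
        ]
    )
    keep.sort()
    return df.iloc[keep]


def cross_validate(
    df: pd.DataFrame,
    y: np.ndarray,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    **rf_params,
) -> tuple[list[ConfusionTable], dict]:
    """Repeated stratified k-fold CV; every example is tested exactly once
    per repeat.  Returns per-fold confusion tables and an MCC/accuracy/AUC
    summary."""
    x, _ = design_matrix(df)
    y = np.asarray(y)
    if k > len(y):
        raise ValueError("more folds than examples")
    tables: list[ConfusionTable] = []
    mccs, accs, aucs = [], [], []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        scores = np.zeros(len(y))
        pred = np.zeros(len(y), dtype=int)
        for train_idx, test_idx in skf.split(x, y):
            model = RandomForestClassifier(random_state=seed + rep, **rf_params)
            model.fit(x[train_idx], y[train_idx])
            pos = list(model.classes_).index(1)
            sc = model.predict_proba(x[test_idx])[:, pos]
            scores[test_idx] = sc
            pred[test_idx] = (sc >= 0.5).astype(int)
            tables.append(confusion_table(y[test_idx], pred[test_idx], 1))
        ct = confusion_table(y, pred, 1)
        try:
            mccs.append(mcc(ct))
        except ValueError:
            pass
        accs.append(accuracy(ct))
        aucs.append(auc(scores, y))
    summary = {
        "mcc": float(np.mean(mccs)) if mccs else float("nan"),
        "accuracy": float(np.mean(accs)),
        "auc": float(np.mean(aucs)),
        "k": k,
        "repeats": repeats,
    }
    return tables, summary


def train_classifier(
    data,
    residue_class: str,
    flip_type: str,
    cfg: RunConfig | None = None,
    seed: int = 0,
    tune: bool = True,
) -> TrainedClassifier:
    """Fit the per-class, per-flip Random Forest.

    *data* is a feature table (or list of LabelledExamples).  Classes are
    balanced by downsampling; the number of features per split is tuned
    by repeated stratified 5-fold CV maximizing the MCC; the ensemble is
    then refitted on all data.
    """
    from .features import features_dataframe

    cfg = cfg or RunConfig()
    df = data if isinstance(data, pd.DataFrame) else features_dataframe(data, cfg)
    task = _task_frame(df, residue_class, flip_type, cfg)
    y = (task["label"] == flip_type).to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    task = _balance(task, y, seed)
    y = (task["label"] == flip_type).to_numpy().astype(int)

    x, names = design_matrix(task)
    p = x.shape[1]
    grid = sorted({max(1, int(round(v))) for v in (np.sqrt(p), p / 3, p / 2)})
    best = None
    cv_summary: dict = {}
    if tune:
        for mf in grid:
            _, summary = cross_validate(
                task, y, k=cfg.cv_folds, repeats=cfg.cv_repeats, seed=seed,
                n_estimators=cfg.n_trees, max_features=mf,
            )
            log.info("tuning %s/%s max_features=%d: MCC %.3f",
                     residue_class, flip_type, mf, summary["mcc"])
            if best is None or summary["mcc"] > best[1]["mcc"]:
                best = (mf, summary)
        mf, cv_summary = best
    else:
        mf = max(1, int(round(np.sqrt(p))))
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees, max_features=mf, random_state=seed
    )
    model.fit(x, y)
    res_max = None
    if flip_type == "tt+":
        res_max = (
            cfg.resolution_max_gly_ttplus
            if residue_class == "X-Gly"
            else cfg.resolution_max_ttplus
        )
    return TrainedClassifier(
        residue_class=residue_class,
        flip_type=flip_type,
        model=model,
        feature_names=names,
        resolution_max=res_max,
        seed=seed,
        cv_summary=cv_summary,
    )


def combine_classifiers(classifiers: list[TrainedClassifier]):
    """Combine the per-flip classifiers of one residue class into a
    multi-label verdict function.

    The verdict is the flip type of the highest-scoring positive
    classifier, or "correct" when none fires; exact score ties break
    towards tt+ (the most common correction) and are logged.
    """
    if not classifiers:
        raise ValueError("no classifiers to combine")
    rc = {c.residue_class for c in classifiers}
    if len(rc) != 1:
        raise ValueError("classifiers must share a residue class")

    def verdict(df: pd.DataFrame):
        all_scores = {c.flip_type: c.predict_score(df) for c in classifiers}
        out = []
        for i in range(len(df)):
            fired = [(ft, s[i]) for ft, s in all_scores.items() if s[i] >= 0.5]
            if not fired:
                out.append(("correct", max(s[i] for s in all_scores.values())))
                continue
            top = max(f[1] for f in fired)
            winners = [ft for ft, s in fired if s == top]
            if len(winners) > 1:
                choice = "tt+" if "tt+" in winners else sorted(winners)[0]
                log.info("tie between %s broken towards %s", winners, choice)
            else:
                choice = winners[0]
            out.append((choice, top))
        return out

    return verdict


def save_classifier(clf: TrainedClassifier, path) -> None:
    import joblib

    joblib.dump(
        {
            "format_version": 1,
            "residue_class": clf.residue_class,
            "flip_type": clf.flip_type,
            "model": clf.model,
            "feature_names": clf.feature_names,
            "resolution_max": clf.resolution_max,
            "seed": clf.seed,
            "cv_summary": clf.cv_summary,
        },
        path,
    )


def load_classifier(path) -> TrainedClassifier:
    import joblib

    d = joblib.load(path)
    return TrainedClassifier(
        residue_class=d["residue_class"],
        flip_type=d["flip_type"],
        model=d["model"],
        feature_names=d["feature_names"],
        resolution_max=d["resolution_max"],
        seed=d["seed"],
        cv_summary=d["cv_summary"],
    )
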