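"""Ensembled scratch classifier and leave-one-subject-out evaluation.

The top layer is a LightGBM binary classifier over the interpretable
feature bank plus ten learned features (five penultimate units from each
of the conv and recurrent extractors).  Feature selection uses recursive
feature elimination by tree gain importance.  Evaluation is
leave-one-subject-out: extractors, feature selection, and the boosted
trees are all re-fit inside each fold so the held-out subject's windows
never influence training, and metrics are reported at the held-out
subject's original class prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .nnets import train_extractor

DEFAULT_K_ACC = 16
DEFAULT_K_BOTH = 18
DL_FEATURE_NAMES = tuple(f"cnn_{i}" for i in range(5)) + tuple(
    f"rnn_{i}" for i in range(5))

_LGB_QUIET = {"verbosity": -1, "verbose": -1}


@dataclass
class EnsembleModel:
    extractors: dict  # kind -> trained extractor
    booster: lgb.LGBMClassifier
    selected_features: list[str]
    sensors: tuple[str, ...]
    hyperparams: dict
    seed: int

    def predict_proba(self, features: pd.DataFrame, nn_input: np.ndarray
                      ) -> np.ndarray:
        full = append_dl_features(features, self.extractors, nn_input)
        return self.booster.predict_proba(full[self.selected_features])[:, 1]


@dataclass
class EvalReport:
    per_fold: pd.DataFrame
    folds: list[dict] = field(default_factory=list)

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.mean(numeric_only=True)

    @property
    def sd(self) -> pd.Series:
        return self.per_fold.std(numeric_only=True)


def train_extractors(nn_input: np.ndarray, labels: np.ndarray,
                     epochs: int = 8, seed: int = 0, **kwargs) -> dict:
    return {
        "conv": train_extractor("conv", nn_input, labels, epochs=epochs,
                                seed=seed, **kwargs),
        "recurrent": train_extractor("recurrent", nn_input, labels,
                                     epochs=epochs, seed=seed + 1, **kwargs),
    }


def derive_dl_features(extractors: dict, nn_input: np.ndarray) -> pd.DataFrame:
    """Ten learned columns: 5 conv + 5 recurrent penultimate activations."""
    cnn = extractors["conv"].features(nn_input)
    rnn = extractors["recurrent"].features(nn_input)
    return pd.DataFrame(np.hstack([cnn, rnn]), columns=list(DL_FEATURE_NAMES))


def append_dl_features(features: pd.DataFrame, extractors: dict,
                       nn_input: np.ndarray) -> pd.DataFrame:
    dl = derive_dl_features(extractors, nn_input)
    dl.index = features.index
    return pd.concat([features, dl], axis=1)


def _fit_booster(X: pd.DataFrame, y: np.ndarray, hyperparams: dict,
                 seed: int, X_val=None, y_val=None) -> lgb.LGBMClassifier:
    clf = lgb.LGBMClassifier(
        n_estimators=hyperparams.get("n_estimators", 200),
        num_leaves=hyperparams.get("num_leaves", 31),
        max_depth=hyperparams.get("max_depth", 6),
        learning_rate=hyperparams.get("learning_rate", 0.1),
        scale_pos_weight=hyperparams.get("scale_pos_weight", 1.0),
        random_state=seed,
        **_LGB_QUIET,
    )
    fit_kw = {}
    if X_val is not None and len(np.unique(y_val)) > 1:
        fit_kw = {"eval_set": [(X_val, y_val)],
                  "callbacks": [lgb.early_stopping(20, verbose=False)]}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y, **fit_kw)
    return clf


def recursive_feature_elimination(
    X: pd.DataFrame, y: np.ndarray, target_k: int,
    step_frac: float = 0.25, seed: int = 0,
    val_frac: float = 0.2, hyperparams: dict | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the lowest-gain features down to ``target_k``.

    Drops ``step_frac`` of the surviving features per round (never past
    ``target_k``) and uses a smaller forest than the final model: the
    ranking, not the classifier, is the product here.  Returns the
    selected feature names and the AUC-versus-size elbow curve measured on
    an internal validation split.
    """
    if target_k > X.shape[1]:
        raise ValueError("target_k exceeds the number of features")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes for feature selection")
    hyperparams = {**(hyperparams or {})}
    hyperparams.setdefault("n_estimators", 60)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(X))
    n_val = max(int(val_frac * len(X)), 1)
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    if len(np.unique(y[val_idx])) < 2 or len(np.unique(y[tr_idx])) < 2:
        tr_idx = val_idx = idx  # degenerate split: score in-sample
    cols = list(X.columns)
    curve = []
    while True:
        clf = _fit_booster(X.iloc[tr_idx][cols], y[tr_idx], hyperparams, seed)
        auc = roc_auc_score(y[val_idx],
                            clf.predict_proba(X.iloc[val_idx][cols])[:, 1])
        curve.append({"n_features": len(cols), "val_auc": float(auc)})
        if len(cols) <= target_k:
            break
        gain = pd.Series(clf.booster_.feature_importance("gain"), index=cols)
        n_drop = min(max(1, int(np.ceil(step_frac * len(cols)))),
                     len(cols) - target_k)
        cols = [c for c in cols
                if c not in set(gain.nsmallest(n_drop).index)]
    return cols, pd.DataFrame(curve)


def train_ensemble(
    features: pd.DataFrame, labels: np.ndarray, nn_input: np.ndarray,
    sensors: tuple[str, ...] = ("acc",),
    target_k: int | None = None,
    hyperparams: dict | None = None,
    epochs: int = 8, seed: int = 0,
    extractors: dict | None = None,
) -> EnsembleModel:
    """Full training: extractors, learned features, RFE, boosted top layer.

    The boosted trees use an 8-2 random train/validation split of the
    training windows for early stopping; ``scale_pos_weight`` balances the
    training set only (evaluation data stay at their own prevalence).
    """
    labels = np.asarray(labels, dtype=int)
    if target_k is None:
        target_k = DEFAULT_K_BOTH if len(sensors) > 1 else DEFAULT_K_ACC
    hyperparams = dict(hyperparams or {})
    if extractors is None:
        extractors = train_extractors(nn_input, labels, epochs=epochs, seed=seed)
    full = append_dl_features(features, extractors, nn_input)

    prev = labels.mean()
    hyperparams.setdefault("scale_pos_weight",
                           float((1 - prev) / prev) if 0 < prev < 1 else 1.0)

    target_k = min(target_k, full.shape[1])
    selected, curve = recursive_feature_elimination(
        full, labels, target_k, seed=seed, hyperparams=hyperparams)

    rng = np.random.default_rng(seed)
    for attempt in range(10):
        idx = rng.permutation(len(full))
        n_val = int(0.2 * len(full))
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        if (len(np.unique(labels[val_idx])) > 1
                and len(np.unique(labels[tr_idx])) > 1):
            break
    booster = _fit_booster(full.iloc[tr_idx][selected], labels[tr_idx],
                           hyperparams, seed,
                           full.iloc[val_idx][selected], labels[val_idx])
    model = EnsembleModel(extractors=extractors, booster=booster,
                          selected_features=selected, sensors=sensors,
                          hyperparams=hyperparams, seed=seed)
    model.rfe_curve = curve
    return model


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Binary confusion-matrix metrics (prevalence, accuracy, recall,
    specificity, F1, PPV, NPV)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    n = tp + tn + fp + fn
    def safe(a, b):
        return float(a / b) if b else float("nan")
    recall = safe(tp, tp + fn)
    ppv = safe(tp, tp + fp)
    f1 = (2 * ppv * recall / (ppv + recall)
          if np.isfinite(ppv) and np.isfinite(recall) and (ppv + recall) > 0
          else 0.0)
    return {"prevalence": safe(tp + fn, n), "accuracy": safe(tp + tn, n),
            "recall": recall, "specificity": safe(tn, tn + fp),
            "f1": float(f1), "ppv": ppv, "npv": safe(tn, tn + fn),
            "tp": tp, "tn": tn, "fp": fp, "fn": fn}


def evaluate_loso(
    features: pd.DataFrame, labels: np.ndarray, subjects: np.ndarray,
    nn_input: np.ndarray,
    sensors: tuple[str, ...] = ("acc",),
    target_k: int | None = None,
    hyperparams: dict | None = None,
    epochs: int = 8, seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """One fold per subject; everything refit per fold; metrics at the
    held-out subject's original prevalence."""
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    labels = np.asarray(labels, dtype=int)
    rows, folds = [], []
    for k, held in enumerate(uniq):
        test = subjects == held
        train = ~test
        model = train_ensemble(
            features[train], labels[train], nn_input[train],
            sensors=sensors, target_k=target_k, hyperparams=hyperparams,
            epochs=epochs, seed=seed + k)
        proba = model.predict_proba(features[test], nn_input[test])
        y_te = labels[test]
        row = {"subject": str(held), **confusion_metrics(y_te, proba >= threshold)}
        if len(np.unique(y_te)) > 1:
            row["auc"] = float(roc_auc_score(y_te, proba))
        else:
            warnings.warn(f"fold {held}: single-class hold-out, AUC undefined")
            row["auc"] = float("nan")
        rows.append(row)
        folds.append({"subject": str(held), "model": model,
                      "proba": proba, "y_true": y_te,
                      "train_subjects": sorted(set(subjects[train]))})
    return EvalReport(per_fold=pd.DataFrame(rows), folds=folds)
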