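"""One-vs-rest random-forest classifiers over GRN feature sets.

One forest per class, trained on a stratified half split. The
classification score of a sample for a class is the fraction of that
class's trees voting for it, so scores live in [0, 1]. Evaluation uses
precision-sensitivity curves with step-wise area (AUPR); AUROC is reported
alongside for reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from grnpipe.grn import ClassGRN

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 1000
    top_k_templates: int = 100
    seed: int = 0


@dataclass
class SplitPlan:
    """Stratified 50/50 split; odd class counts favor training."""

    train_ids: list[str]
    valid_ids: list[str]


@dataclass
class ClassifierModel:
    """Per class: a trained forest, its feature gene list, and importances."""

    forests: dict[str, RandomForestClassifier]
    features: dict[str, list[str]]
    importances: dict[str, pd.Series]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = sorted(self.forests)


@dataclass
class PRCurve:
    """Precision-sensitivity points ordered by descending cutoff, plus the
    step-wise area under the curve."""

    cutoffs: np.ndarray
    precision: np.ndarray
    sensitivity: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "precision": self.precision,
                "sensitivity": self.sensitivity,
            }
        )


def split_half(table: pd.DataFrame, seed: int = 0) -> SplitPlan:
    """Stratified 50/50 split of the sample table by class annotation.

    Each class contributes ceil(n/2) samples to training and the rest to
    validation; deterministic under seed. Raises on singleton classes.
    """
    counts = table["description"].value_counts()
    singles = counts[counts < 2]
    if len(singles) > 0:
        raise ValueError(f"class with a single sample: {list(singles.index)}")
    rng = np.random.default_rng([seed, 10])
    train: list[str] = []
    valid: list[str] = []
    for cls in sorted(counts.index):
        ids = table.loc[table["description"] == cls, "sample_id"].tolist()
        perm = rng.permutation(len(ids))
        n_train = (len(ids) + 1) // 2  # odd count: extra sample trains
        train.extend(ids[i] for i in perm[:n_train])
        valid.extend(ids[i] for i in perm[n_train:])
    return SplitPlan(sorted(train), sorted(valid))


def train_classifiers(
    expr_train: pd.DataFrame,
    labels: pd.Series,
    class_grns: dict[str, ClassGRN],
    templates: pd.DataFrame,
    config: ClassifierConfig = ClassifierConfig(),
) -> ClassifierModel:
    """Train one one-vs-rest forest per class.

    The feature set of a class is its GRN genes union the top template
    genes (the template fallback guarantees a non-empty feature set when a
    GRN is empty). Per-gene forest importances are stored and written back
    to each ClassGRN as weights normalized to sum 1 over its genes.
    """
    labels = labels.reindex(expr_train.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some training columns")
    forests: dict[str, RandomForestClassifier] = {}
    features: dict[str, list[str]] = {}
    importances: dict[str, pd.Series] = {}
    present = set(expr_train.index)
    for k, cls in enumerate(sorted(class_grns)):
        grn = class_grns[cls]
        top = templates[cls].nlargest(config.top_k_templates).index if cls in templates else []
        feats = sorted((set(grn.genes) | set(top)) & present)
        if not feats:
            raise ValueError(f"no features available for class {cls}")
        X = expr_train.loc[feats].to_numpy(dtype=float).T
        y = (labels == cls).to_numpy()
        if not y.any():
            raise ValueError(f"no training samples for class {cls}")
        seed = int(np.random.SeedSequence([config.seed, 20, k]).generate_state(1)[0])
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
        forest.fit(X, y)
        imp = pd.Series(forest.feature_importances_, index=feats)
        forests[cls] = forest
        features[cls] = feats
        importances[cls] = imp
        # propagate importances to GRN weights, normalized to sum 1
        w = imp.reindex(grn.genes, fill_value=0.0).astype(float)
        if len(w) > 0:
            w = w + 0.0
            total = w.sum()
            grn.importances = w / total if total > 0 else w * 0 + 1.0 / len(w)
    return ClassifierModel(forests, features, importances)


def classify(model: ClassifierModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Score samples against every class's forest.

    Returns a class-by-sample matrix of scores in [0, 1] (fraction of trees
    voting for the class). Feature genes missing from the query matrix are
    imputed at 0 with a warning.
    """
    scores = np.zeros((len(model.classes), expr.shape[1]))
    for i, cls in enumerate(model.classes):
        feats = model.features[cls]
        missing = [g for g in feats if g not in expr.index]
        if missing:
            logger.warning(
                "class %s: %d feature genes missing from query, imputing 0",
                cls,
                len(missing),
            )
        X = expr.reindex(feats, fill_value=0.0).to_numpy(dtype=float).T
        proba = model.forests[cls].predict_proba(X)
        pos = list(model.forests[cls].classes_).index(True)
        scores[i] = proba[:, pos]
    return pd.DataFrame(scores, index=model.classes, columns=expr.columns)


def pr_curve(scores: np.ndarray | pd.Series, truth: np.ndarray | pd.Series) -> PRCurve:
    """Precision-sensitivity curve over all distinct score cutoffs.

    At cutoff c a sample is called positive when score >= c. Precision with
    zero calls is 1 by convention, so the curve starts at sensitivity 0.
    The area is integrated step-wise: sum of precision times the
    sensitivity increment, over cutoffs in descending order.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and truth must have the same length")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("truth has no positive samples")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp_cum = np.cumsum(y_sorted)
    calls = np.arange(1, len(s) + 1)
    # keep the last index of each distinct score (all samples >= that score)
    last = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]

    cutoffs = np.concatenate(([np.inf], s_sorted[last]))
    precision = np.concatenate(([1.0], tp_cum[last] / calls[last]))
    sensitivity = np.concatenate(([0.0], tp_cum[last] / n_pos))
    auc = float(np.sum(np.diff(sensitivity) * precision[1:]))
    return PRCurve(cutoffs, precision, sensitivity, auc)


def evaluate_all(
    model: ClassifierModel,
    expr_valid: pd.DataFrame,
    labels_valid: pd.Series,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Per-class precision-sensitivity curves with bootstrap AUPR CIs.

    Returns a dict with per-class PRCurve, AUPR point estimates, percentile
    95% bootstrap confidence intervals (stratified resampling of validation
    samples so every draw keeps at least one positive), AUROC for
    reference, and the mean AUPR over classes.
    """
    labels_valid = labels_valid.reindex(expr_valid.columns)
    scores = classify(model, expr_valid)
    rng = np.random.default_rng([seed, 30])
    curves: dict[str, PRCurve] = {}
    auprs: dict[str, float] = {}
    aurocs: dict[str, float] = {}
    cis: dict[str, tuple[float, float]] = {}
    for cls in model.classes:
        y = (labels_valid == cls).to_numpy()
        if not y.any():
            raise ValueError(f"no validation samples for class {cls}")
        s = scores.loc[cls].to_numpy()
        curve = pr_curve(s, y)
        curves[cls] = curve
        auprs[cls] = curve.auc
        aurocs[cls] = float(roc_auc_score(y, s)) if 0 < y.sum() < len(y) else 1.0
        pos_idx = np.nonzero(y)[0]
        neg_idx = np.nonzero(~y)[0]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate(
                [
                    rng.choice(pos_idx, size=len(pos_idx), replace=True),
                    rng.choice(neg_idx, size=len(neg_idx), replace=True)
                    if len(neg_idx)
                    else np.empty(0, dtype=int),
                ]
            )
            boots[b] = pr_curve(s[take], y[take]).auc
        lo, hi = np.percentile(boots, [2.5, 97.5])
        cis[cls] = (float(lo), float(hi))
    return {
        "curves": curves,
        "aupr": auprs,
        "auroc": aurocs,
        "ci": cis,
        "mean_aupr": float(np.mean(list(auprs.values()))),
        "mean_auroc": float(np.mean(list(aurocs.values()))),
    }
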