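"""Classifier benchmarking on retained features with repeated hold-out.

Three models are evaluated: an RBF-kernel support vector machine, a random
forest, and a bagging ensemble of back-propagation multilayer perceptrons
("BP bagging": each base network sees a random subset of the features and
of the training epochs, and predictions are combined by majority vote).

Evaluation uses repeated stratified hold-out at epoch level (default 10
repeats of an 80/20 split).  Feature standardisation is fitted on the
training portion of each split only; the random forest receives raw
features.  A subject-wise split mode keeps all epochs of a subject on one
side of the split, which avoids the optimism created by 50 %-overlap
epochs of one subject appearing in both train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit, GroupShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureTable
from .montage import BAND_NAMES
from .select import SelectionResult

MODEL_KINDS = ("svm_rbf", "random_forest", "bp_bagging")
POSITIVE_LABEL = "GAD"
NEGATIVE_LABEL = "HC"


@dataclass
class ModelSpec:
    """Configuration of one classifier.

    SVM cost/width and network training details are exposed because they
    are conventional rather than canonical; the ensemble geometry (100 base
    networks of 6 x 100 rectified-linear hidden units, 80 % feature and
    sample perturbation, majority vote) matches the benchmarked design.
    """

    kind: str
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    rf_trees: int = 500
    bpb_n_base: int = 100
    bpb_hidden_layers: int = 6
    bpb_neurons: int = 100
    bpb_feature_frac: float = 0.8
    bpb_sample_frac: float = 0.8
    bpb_max_iter: int = 200

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}")
        for frac in (self.bpb_feature_frac, self.bpb_sample_frac):
            if not 0 < frac <= 1:
                raise ValueError("perturbation fractions must lie in (0, 1]")
        for count in (self.rf_trees, self.bpb_n_base, self.bpb_hidden_layers,
                      self.bpb_neurons):
            if count < 1:
                raise ValueError("counts must be >= 1")


class BpBaggingClassifier(BaseEstimator, ClassifierMixin):
    """Bagging ensemble of multilayer perceptrons with feature perturbation.

    Each base learner is an MLP trained on a random ``sample_frac`` subset
    of the training epochs and a random ``feature_frac`` subset of the
    feature columns (both redrawn per learner).  Prediction is a majority
    vote; ties are broken toward the negative ("HC") label.
    """

    def __init__(
        self,
        n_base: int = 100,
        hidden_layers: int = 6,
        neurons: int = 100,
        feature_frac: float = 0.8,
        sample_frac: float = 0.8,
        max_iter: int = 200,
        random_state: int | None = None,
    ):
        self.n_base = n_base
        self.hidden_layers = hidden_layers
        self.neurons = neurons
        self.feature_frac = feature_frac
        self.sample_frac = sample_frac
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.random_state)
        n, p = X.shape
        n_feat = max(1, int(np.ceil(self.feature_frac * p)))
        n_samp = max(2, int(np.ceil(self.sample_frac * n)))
        self.estimators_: list[MLPClassifier] = []
        self.feature_subsets_: list[np.ndarray] = []
        for _ in range(self.n_base):
            feats = np.sort(rng.choice(p, size=n_feat, replace=False))
            while True:  # redraw until both classes are present
                rows = rng.choice(n, size=n_samp, replace=False)
                if len(np.unique(y[rows])) == len(self.classes_):
                    break
            net = MLPClassifier(
                hidden_layer_sizes=(self.neurons,) * self.hidden_layers,
                activation="relu",
                solver="adam",
                # validation-based early stopping only where the 10 % slice
                # is large enough to be a reliable stopping signal
                early_stopping=n_samp >= 1000,
                validation_fraction=0.1,
                n_iter_no_change=25,
                max_iter=self.max_iter,
                random_state=int(rng.integers(2**31 - 1)),
            )
            net.fit(X[rows][:, feats], y[rows])
            self.estimators_.append(net)
            self.feature_subsets_.append(feats)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        votes = np.stack(
            [
                net.predict(X[:, feats])
                for net, feats in zip(self.estimators_, self.feature_subsets_)
            ]
        )
        out = np.empty(X.shape[0], dtype=votes.dtype)
        for i in range(X.shape[0]):
            labels, counts = np.unique(votes[:, i], return_counts=True)
            top = counts.max()
            winners = set(labels[counts == top])
            if len(winners) > 1 and NEGATIVE_LABEL in winners:
                out[i] = NEGATIVE_LABEL
            else:
                out[i] = labels[np.argmax(counts)]
        return out


def build_model(spec: ModelSpec, seed: int):
    """Instantiate the estimator (with its preprocessing) for a spec."""
    if spec.kind == "svm_rbf":
        return make_pipeline(
            StandardScaler(), SVC(C=spec.svm_c, gamma=spec.svm_gamma, kernel="rbf")
        )
    if spec.kind == "random_forest":
        return RandomForestClassifier(n_estimators=spec.rf_trees, random_state=seed)
    return make_pipeline(
        StandardScaler(),
        BpBaggingClassifier(
            n_base=spec.bpb_n_base,
            hidden_layers=spec.bpb_hidden_layers,
            neurons=spec.bpb_neurons,
            feature_frac=spec.bpb_feature_frac,
            sample_frac=spec.bpb_sample_frac,
            max_iter=spec.bpb_max_iter,
            random_state=seed,
        ),
    )


def bp_bagging_train(X, y, spec: ModelSpec, seed: int = 0):
    """Fit the standardiser + MLP-bagging ensemble on a training set."""
    if spec.kind != "bp_bagging":
        raise ValueError("spec.kind must be 'bp_bagging'")
    n_feat = int(np.ceil(spec.bpb_feature_frac * np.asarray(X).shape[1]))
    if n_feat < 1:
        raise ValueError("feature subset would be empty")
    model = build_model(spec, seed)
    return model.fit(X, y)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and F1 from a confusion matrix.

    Positive class is the patient group.  A metric whose denominator is
    zero is undefined and returned as NaN.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion-matrix counts must be >= 0")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, fp + tn),
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
    }


def confusion_counts(y_true, y_pred, positive: str = POSITIVE_LABEL) -> dict[str, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    pred_pos = y_pred == positive
    return {
        "tp": int(np.sum(pos & pred_pos)),
        "fp": int(np.sum(~pos & pred_pos)),
        "fn": int(np.sum(pos & ~pred_pos)),
        "tn": int(np.sum(~pos & ~pred_pos)),
    }


@dataclass
class EvalReport:
    """Repeated hold-out evaluation summary for one model and feature set."""

    model_kind: str
    per_repeat: list[dict[str, int]]
    metrics_mean: dict[str, float]
    metrics_sd: dict[str, float]
    n_repeats: int
    test_frac: float
    seed: int
    n_features: int
    subject_split: bool = False
    label: str = "all"

    def to_row(self) -> dict:
        row = {"model": self.model_kind, "subset": self.label,
               "n_features": self.n_features}
        for k in ("accuracy", "sensitivity", "specificity", "f1"):
            row[f"{k}_mean"] = self.metrics_mean[k]
            row[f"{k}_sd"] = self.metrics_sd[k]
        return row


def _splits(y, groups, n_repeats, test_frac, seed, subject_split):
    if subject_split:
        splitter = GroupShuffleSplit(
            n_splits=n_repeats, test_size=test_frac, random_state=seed
        )
        yield from splitter.split(np.zeros(len(y)), y, groups=groups)
    else:
        splitter = StratifiedShuffleSplit(
            n_splits=n_repeats, test_size=test_frac, random_state=seed
        )
        yield from splitter.split(np.zeros(len(y)), y)


def holdout_eval(
    table: FeatureTable,
    selected: SelectionResult | np.ndarray,
    spec: ModelSpec,
    n_repeats: int = 10,
    test_frac: float = 0.2,
    seed: int = 0,
    subject_split: bool = False,
    label: str = "all",
    labels_override: np.ndarray | None = None,
) -> EvalReport:
    """Repeated stratified hold-out evaluation of one model.

    ``selected`` may be a SelectionResult or a boolean column mask; only
    retained columns enter the model.  Standardisation (where the model
    uses it) is fitted inside each training fold, so the test portion never
    influences the scaler.  ``labels_override`` substitutes the group
    labels (e.g. a permutation for a chance-level control).
    """
    mask = selected.mask if isinstance(selected, SelectionResult) else np.asarray(selected)
    if mask.sum() < 1:
        raise ValueError("no retained features to classify on")
    X = table.values[:, mask]
    y = table.row_meta["group"].to_numpy() if labels_override is None else np.asarray(labels_override)
    if len(np.unique(y)) != 2:
        raise ValueError("need both class labels")
    groups = table.row_meta["subject_id"].to_numpy()

    rng = np.random.default_rng(seed)
    per_repeat: list[dict[str, int]] = []
    rows: list[dict[str, float]] = []
    for rep, (tr, te) in enumerate(
        _splits(y, groups, n_repeats, test_frac, seed, subject_split)
    ):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            # degenerate split (possible with grouped splitting): resample
            perm = rng.permutation(len(y))
            cut = len(te)
            te, tr = perm[:cut], perm[cut:]
        model = build_model(spec, seed=int(rng.integers(2**31 - 1)))
        model.fit(X[tr], y[tr])
        cm = confusion_counts(y[te], model.predict(X[te]))
        per_repeat.append(cm)
        rows.append(compute_metrics(**cm))

    names = ("accuracy", "sensitivity", "specificity", "f1")
    arr = {k: np.array([r[k] for r in rows]) for k in names}
    return EvalReport(
        model_kind=spec.kind,
        per_repeat=per_repeat,
        metrics_mean={k: float(np.nanmean(v)) for k, v in arr.items()},
        metrics_sd={k: float(np.nanstd(v, ddof=1)) for k, v in arr.items()},
        n_repeats=n_repeats,
        test_frac=test_frac,
        seed=seed,
        n_features=int(mask.sum()),
        subject_split=subject_split,
        label=label,
    )


def per_band_eval(
    table: FeatureTable,
    selected: SelectionResult,
    spec: ModelSpec,
    bands: tuple[str, ...] = BAND_NAMES,
    **kwargs,
) -> dict[str, EvalReport | None]:
    """Evaluate on all retained features and on each band's retained subset.

    A band with no retained features is reported as ``None`` (skipped).
    """
    out: dict[str, EvalReport | None] = {
        "all": holdout_eval(table, selected, spec, label="all", **kwargs)
    }
    for band in bands:
        mask = selected.band_mask(band)
        if mask.sum() == 0:
            out[band] = None
            continue
        out[band] = holdout_eval(table, mask, spec, label=band, **kwargs)
    return out


def reports_to_frame(reports: dict[str, dict[str, EvalReport | None]]) -> pd.DataFrame:
    """Flatten {model -> {subset -> report}} into a tidy metrics table."""
    rows = []
    for model, by_subset in reports.items():
        for subset, rep in by_subset.items():
            if rep is None:
                rows.append({"model": model, "subset": subset, "n_features": 0})
            else:
                rows.append(rep.to_row())
    return pd.DataFrame(rows)
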