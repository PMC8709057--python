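"""P300 SVM classifiers, metric suite, and attack-impact evaluation.

Five kernels are supported, mirroring a standard classification-tool
preset family: linear (L), quadratic (Q), cubic (C), medium Gaussian (MG)
and coarse Gaussian (CG). Gaussian kernel scales follow the preset
convention ``scale = sqrt(P)`` (MG) and ``4·sqrt(P)`` (CG) with P the
feature count, i.e. ``gamma = 1/P`` and ``1/(16P)``; polynomial kernels use
``(x·y/P + 1)^degree``. The box constraint defaults to 1.

Metrics (P300 = positive class)::

    A   = (TP + TN) / (TP + TN + FP + FN)
    PPV = TP / (TP + FP)
    TPR = TP / (TP + FN)
    F1  = 2·PPV·TPR / (PPV + TPR)

and the cyberattack impact ``Δ = V_real − V_fake`` per metric. Metrics with
a zero denominator are flagged as undefined (``None``), never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from . import bhr as bhr_mod
from .attacks import HackedDataset
from .exceptions import DataError
from .prep import PrepConfig, features_matrix
from .synthgen import NONP300_LABEL, P300_LABEL

__all__ = [
    "KERNELS",
    "KernelSpec",
    "MetricsReport",
    "ImpactReport",
    "TrainedModel",
    "make_svc",
    "train_svm",
    "predict_labels",
    "evaluate",
    "metrics_from_counts",
    "cyberattack_impact",
    "evaluate_under_attack",
]

KERNELS = ("L", "Q", "C", "MG", "CG")

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class KernelSpec:
    """One of the five kernel presets."""

    kind: str
    box_constraint: float = 1.0

    def __post_init__(self):
        if self.kind not in KERNELS:
            raise ValueError(f"unknown kernel {self.kind!r}; expected one of {KERNELS}")

    def svc_params(self, n_features: int) -> dict:
        p = float(n_features)
        common = dict(C=self.box_constraint, cache_size=200)
        if self.kind == "L":
            return dict(kernel="linear", **common)
        if self.kind == "Q":
            return dict(kernel="poly", degree=2, gamma=1.0 / p, coef0=1.0, **common)
        if self.kind == "C":
            return dict(kernel="poly", degree=3, gamma=1.0 / p, coef0=1.0, **common)
        if self.kind == "MG":  # kernel scale sqrt(P)
            return dict(kernel="rbf", gamma=1.0 / p, **common)
        # CG: kernel scale 4*sqrt(P)
        return dict(kernel="rbf", gamma=1.0 / (16.0 * p), **common)


@dataclass
class MetricsReport:
    """Confusion counts plus the derived metric suite."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    #: names of metrics whose denominator was zero
    undefined: tuple = ()

    @property
    def n_trials(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
        }


@dataclass
class ImpactReport:
    """Per-metric cyberattack impact Δ = V_real − V_fake."""

    deltas: dict

    def __getitem__(self, key):
        return self.deltas[key]


@dataclass
class TrainedModel:
    """A fitted SVC plus its training descriptor."""

    kernel: KernelSpec
    estimator: SVC
    cv_accuracy: float
    k_folds: int
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != training dimension {self.n_features}"
            )
        return self.estimator.predict(X)


def make_svc(kernel: KernelSpec | str, n_features: int) -> SVC:
    if isinstance(kernel, str):
        kernel = KernelSpec(kernel)
    return SVC(**kernel.svc_params(n_features))


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    kernel: KernelSpec | str = "L",
    k_folds: int | None = 5,
    seed: int = 0,
) -> TrainedModel:
    """Fit one SVM with stratified k-fold cross-validated accuracy.

    The reported ``cv_accuracy`` is the mean held-out-fold accuracy; the
    returned estimator is refit on the full training set. Deterministic
    given ``seed`` (it fixes the fold shuffle). ``k_folds=None`` skips
    cross-validation (``cv_accuracy`` is NaN).
    """
    if isinstance(kernel, str):
        kernel = KernelSpec(kernel)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("training labels contain a single class")
    est = make_svc(kernel, X.shape[1])
    if k_folds:
        cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        cv_acc = float(cross_val_score(est, X, y, cv=cv, scoring="accuracy").mean())
    else:
        cv_acc = float("nan")
    est.fit(X, y)
    return TrainedModel(
        kernel=kernel, estimator=est, cv_accuracy=cv_acc,
        k_folds=k_folds or 0, n_features=X.shape[1],
    )


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    """Metric suite from a confusion quadruple; zero denominators flagged."""
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    acc = ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    ppv = ratio(tp, tp + fp, "precision")
    tpr = ratio(tp, tp + fn, "recall")
    if ppv is None or tpr is None or (ppv + tpr) == 0:
        undefined.append("f1")
        f1 = None
    else:
        f1 = 2.0 * ppv * tpr / (ppv + tpr)
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=acc, precision=ppv, recall=tpr, f1=f1,
        undefined=tuple(undefined),
    )


def _counts(y_true: np.ndarray, y_pred: np.ndarray):
    pos = P300_LABEL
    tp = int(np.sum((y_pred == pos) & (y_true == pos)))
    tn = int(np.sum((y_pred != pos) & (y_true != pos)))
    fp = int(np.sum((y_pred == pos) & (y_true != pos)))
    fn = int(np.sum((y_pred != pos) & (y_true == pos)))
    return tp, tn, fp, fn


def predict_labels(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def evaluate(model: TrainedModel, X: np.ndarray, y: np.ndarray) -> MetricsReport:
    """Confusion counts and metrics of ``model`` on labelled features."""
    y = np.asarray(y)
    y_pred = model.predict(X)
    return metrics_from_counts(*_counts(y, y_pred))


def cyberattack_impact(real: MetricsReport, fake: MetricsReport) -> ImpactReport:
    """Δ = V_real − V_fake per metric, on the metric's own scale.

    A delta involving an undefined metric is itself ``None``.
    """
    deltas = {}
    for name in METRIC_NAMES:
        v_real = getattr(real, name)
        v_fake = getattr(fake, name)
        deltas[name] = None if v_real is None or v_fake is None else v_real - v_fake
    return ImpactReport(deltas=deltas)


def bhr_filter(
    hacked: HackedDataset,
    prep_cfg: PrepConfig = PrepConfig(),
    bhr_cfg: bhr_mod.BHRConfig | None = None,
    bhr_seed: int = 0,
    attacker_seed: int = 1,
):
    """Run every trial of a hacked dataset through the integrity layer.

    Each trial travels encode → decode_verify with a fresh defender tuple
    per trial (synchronized PRNG at ``bhr_seed``). Legitimate trials are
    encoded with the true tuple; forged trials are re-encoded by the
    attacker under an independent, uniformly guessed tuple. Returns
    ``(forced, X, positions)`` where ``forced`` marks compromised trials
    (to be inhibited) and ``X`` holds features of the reconstructed,
    verified trials at ``positions``. Shared by every kernel so the
    encode/decode/preprocessing pass runs once per dataset.
    """
    from .prep import extract_features  # local import to avoid cycle at module load

    trials = hacked.trials
    cfg = bhr_cfg or bhr_mod.BHRConfig(n_channels=trials[0].n_channels)
    m = bhr_mod.n_arrangements(cfg.n_channels)
    atk_rng = np.random.default_rng(attacker_seed)
    fake_set = set(int(i) for i in hacked.substituted_indices)

    forced = np.zeros(len(trials), dtype=bool)
    feats, feat_pos = [], []
    for i, trial in enumerate(trials):
        true_t = bhr_mod.tuple_for(bhr_seed, i, cfg.n_channels)
        if i in fake_set:
            guess = bhr_mod.tuple_from_index(int(atk_rng.integers(m)), cfg.n_channels)
            sent = bhr_mod.forge(trial.data, guess, cfg)
        else:
            sent = bhr_mod.encode(trial.data, true_t, cfg)
        res = bhr_mod.decode_verify(sent, true_t, cfg)
        if res.compromised:
            forced[i] = True
        else:
            feats.append(
                extract_features(trial.copy(data=res.frame), prep_cfg).values
            )
            feat_pos.append(i)
    X = np.stack(feats) if feats else np.empty((0, 0))
    return forced, X, np.array(feat_pos, dtype=int)


def evaluate_under_attack(
    model: TrainedModel,
    hacked: HackedDataset,
    prep_cfg: PrepConfig = PrepConfig(),
    bhr_enabled: bool = False,
    bhr_cfg: bhr_mod.BHRConfig | None = None,
    bhr_seed: int = 0,
    attacker_seed: int = 1,
) -> MetricsReport:
    """Evaluate a model on a hacked dataset, optionally behind the BHR.

    With the BHR enabled (see :func:`bhr_filter`), a compromised verdict
    forces the non-P300 label (inhibition); verified frames are
    reconstructed (channel d policy-filled) and then classified normally.
    """
    trials = hacked.trials
    y_true = np.array([t.label for t in trials])
    if not bhr_enabled:
        X, _ = features_matrix(trials, prep_cfg)
        y_pred = model.predict(X)
        return metrics_from_counts(*_counts(y_true, y_pred))

    forced, X, feat_pos = bhr_filter(hacked, prep_cfg, bhr_cfg, bhr_seed, attacker_seed)
    y_pred = np.full(len(trials), NONP300_LABEL, dtype=object)
    if len(feat_pos):
        y_pred[feat_pos] = model.predict(X)
    # inhibition: forced slots already nonP300
    return metrics_from_counts(*_counts(y_true, y_pred.astype(str)))
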