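"""Residual-CNN features + cubic-kernel SVM, and the ablation classifiers.

The selected representative images are embedded by a small residual CNN
(two residual blocks, global average pooling) trained briefly as a
classifier on the training split; its penultimate pooled features feed a
degree-3 polynomial ("cubic") SVM with box constraint C = 1 and kernel
scale 1/(d * Var[x]) — the Classification-Learner-style "Auto" scale,
which is sklearn's ``gamma="scale"``.  Platt scaling supplies calibrated
probabilities for the calibration and decision-curve analyses.

Ablation alternatives share the same interface: a logistic-regression
head on the same residual features, and a "direct logits" SVM fed the
class-based feature vectors with the rendering stage bypassed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from . import nnet
from .backbone import feature_columns

logger = logging.getLogger(__name__)


@dataclass
class SvmSpec:
    """Cubic-kernel SVM settings (polynomial degree 3, C = 1, auto scale,
    one-vs-one, Platt-calibrated probabilities)."""

    kernel_degree: int = 3
    box_constraint: float = 1.0
    kernel_scale: str = "auto"   # gamma = 1/(d * Var[x])
    coef0: float = 1.0
    seed: int = 42


class ClassifierModel:
    """Uniform wrapper over fitted sklearn estimators.

    Exposes hard labels, real-valued decision scores and calibrated
    probabilities; ``classes_`` fixes the column order of probability
    outputs.
    """

    def __init__(self, estimator, feature_fn=None):
        self.estimator = estimator
        self.feature_fn = feature_fn or (lambda x: np.asarray(x))
        self.classes_ = list(estimator.classes_)

    def predict(self, x):
        return self.estimator.predict(self.feature_fn(x))

    def predict_proba(self, x):
        return self.estimator.predict_proba(self.feature_fn(x))

    def decision_scores(self, x):
        f = self.feature_fn(x)
        if hasattr(self.estimator, "decision_function"):
            return self.estimator.decision_function(f)
        p = self.estimator.predict_proba(f)
        return p[:, 1] if p.shape[1] == 2 else p


class ResidualFeatureExtractor:
    """Small residual CNN; penultimate pooled features, fixed width.

    Trained briefly as a classifier on the training-split images (the
    head is dropped afterwards); evaluation-mode inference is
    deterministic.  Input images are bilinearly rescaled to
    ``input_size`` and may be [-1, 1] renders or 8-bit arrays.
    """

    def __init__(self, width=32, input_size=32, seed=42):
        self.width = width
        self.input_size = input_size
        self.seed = seed
        self.net = None
        self.head = None
        self.classes = None

    def _build(self, rng):
        w = self.width
        c1 = max(8, w // 4)
        c2 = max(16, w // 2)

        def block(c):
            return nnet.Residual(nnet.Sequential([
                nnet.Conv2d(c, c, rng), nnet.ReLU(),
                nnet.Conv2d(c, c, rng)]))

        self.net = nnet.Sequential([
            nnet.Conv2d(1, c1, rng, stride=2), nnet.ReLU(),
            block(c1), nnet.ReLU(),
            nnet.Conv2d(c1, c2, rng, stride=2), nnet.ReLU(),
            block(c2), nnet.ReLU(),
            nnet.Conv2d(c2, w, rng, stride=2), nnet.ReLU(),
            nnet.GlobalAvgPool2d(),
        ])

    def _prep(self, images):
        out = np.empty((len(images), 1, self.input_size, self.input_size),
                       dtype=np.float32)
        for i, img in enumerate(images):
            a = np.asarray(img, dtype=np.float64)
            if a.ndim == 3:
                a = a.mean(axis=2)
            if a.max() > 1.5:  # 8-bit input -> [-1, 1]
                a = a / 127.5 - 1.0
            if a.shape != (self.input_size, self.input_size):
                a = resize(a, (self.input_size, self.input_size), order=1,
                           anti_aliasing=True, preserve_range=True)
            out[i, 0] = a
        return out

    def fit(self, images, labels, epochs=6, lr=1e-3, batch_size=32):
        self.classes = sorted(set(labels))
        if len(self.classes) < 2:
            raise ValueError("extractor training needs two classes")
        rng = np.random.default_rng(self.seed)
        self._build(rng)
        self.head = nnet.Dense(self.width, len(self.classes), rng,
                               init="glorot")
        full = nnet.Sequential([self.net, self.head])
        opt = nnet.Adam(full.params, full.grads, lr=lr)
        x = self._prep(images)
        y = np.array([self.classes.index(l) for l in labels])
        n = len(x)
        for epoch in range(epochs):
            order = rng.permutation(n)
            for i in range(0, n, batch_size):
                idx = order[i:i + batch_size]
                logits = full.forward(x[idx])
                loss, dlogits = nnet.softmax_cross_entropy(logits, y[idx])
                full.backward(dlogits)
                opt.step()
            logger.debug("residual extractor epoch %d loss %.4f", epoch,
                         loss)
        return self

    def transform(self, images, batch=256):
        if self.net is None:
            raise RuntimeError("extractor is not initialized; call fit()")
        x = self._prep(images)
        return np.concatenate([self.net.forward(x[i:i + batch])
                               for i in range(0, len(x), batch)])


def extract_residual_features(images, extractor) -> np.ndarray:
    """One fixed-width feature vector per image (deterministic)."""
    return extractor.transform(list(images))


def train_svm(features, labels, spec: SvmSpec | None = None) \
        -> ClassifierModel:
    """Cubic-kernel one-vs-one SVM with Platt-calibrated probabilities."""
    spec = spec or SvmSpec()
    features = np.asarray(features, dtype=np.float64)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    if len(set(labels)) < 2:
        raise ValueError("SVM training needs at least two classes")
    svc = SVC(kernel="poly", degree=spec.kernel_degree,
              C=spec.box_constraint, gamma="scale", coef0=spec.coef0,
              probability=True, decision_function_shape="ovo",
              random_state=spec.seed)
    with warnings.catch_warnings():
        # SVC(probability=True) is libsvm's built-in Platt scaling; its
        # pending deprecation alias does not change the fitted model
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(features, list(labels))
    return ClassifierModel(svc)


def train_logreg(features, labels, seed=42) -> ClassifierModel:
    """L2-regularized maximum-likelihood linear classifier."""
    if len(set(labels)) < 2:
        raise ValueError("logistic regression needs at least two classes")
    lr = LogisticRegression(max_iter=2000, random_state=seed)
    lr.fit(np.asarray(features, dtype=np.float64), list(labels))
    return ClassifierModel(lr)


def classify_direct_logits(feature_table, labels=None,
                           spec: SvmSpec | None = None,
                           use_raw_logits=True) -> ClassifierModel:
    """Rendering bypassed: SVM on the K class-based feature columns.

    Uses the retained raw logits columns when present (the values the
    head produced before softmax), falling back to the probability
    columns.
    """
    kind = "logit" if (use_raw_logits
                       and feature_columns(feature_table, "logit")) \
        else "prob"
    cols = feature_columns(feature_table, kind)
    if not cols:
        raise ValueError("feature table has no class-based feature columns")
    x = feature_table[cols].to_numpy(dtype=np.float64)
    if labels is None:
        labels = list(feature_table["label"])
    model = train_svm(x, labels, spec)
    model.feature_columns = cols
    return model
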