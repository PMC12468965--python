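"""Trainable image backbone and class-based (logits-layer) features.

A classification head with one output per class is trained jointly with
the backbone; the per-class softmax probabilities of that head are the
"class-based features" carried forward (F1 = probability of class #1,
F2 = probability of class #2, ...).  The raw pre-softmax logits are kept
alongside for the direct-logits ablation, and the penultimate
(pre-logits) representation is exposed as the dense "FC" feature block.

The testable default backbone is a small from-scratch CNN (three
stride-2 conv blocks, global average pooling, linear head) trained with
Adam on cross-entropy.  Pretrained transformer checkpoints can be
adapted behind the same contract but require external weights and are
not part of the test surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import nnet

logger = logging.getLogger(__name__)


@dataclass
class BackboneSpec:
    """Training hyperparameters of the image classifier."""

    name: str = "ref_cnn"
    loss: str = "cross_entropy"
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    epochs: int = 15
    batch_size: int = 32
    input_size: int = 64
    seed: int = 42
    channels: tuple = (16, 32, 64)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.loss != "cross_entropy" or self.optimizer != "adam":
            raise ValueError("only cross_entropy loss with adam is supported")


def _to_array(images):
    """Accept CohortImage objects or raw arrays; return list of 2-D/3-D uint8."""
    out = []
    for im in images:
        a = im.pixels if hasattr(im, "pixels") else np.asarray(im)
        out.append(np.asarray(a))
    return out


def preprocess(images, input_size):
    """Resize to (input_size, input_size), scale to [0,1], channels-first RGB.

    Grayscale inputs are replicated across channels; size mismatches are
    always resolved by bilinear resize, never by cropping.
    """
    batch = np.empty((len(images), 3, input_size, input_size),
                     dtype=np.float32)
    for i, a in enumerate(_to_array(images)):
        a = a.astype(np.float32) / 255.0
        if a.ndim == 2:
            a = np.repeat(a[:, :, None], 3, axis=2)
        if a.shape[0] != input_size or a.shape[1] != input_size:
            a = resize(a, (input_size, input_size, 3), order=1,
                       anti_aliasing=True, preserve_range=True)
        batch[i] = a.transpose(2, 0, 1)
    return batch


class BackboneModel:
    """Small reference CNN with a K-way logits head."""

    def __init__(self, spec: BackboneSpec, classes):
        self.spec = spec
        self.classes = list(classes)
        rng = np.random.default_rng(spec.seed)
        c1, c2, c3 = spec.channels
        self.fc_width = c3
        self.body = nnet.Sequential([
            nnet.Conv2d(3, c1, rng, stride=2), nnet.ReLU(),
            nnet.Conv2d(c1, c2, rng, stride=2), nnet.ReLU(),
            nnet.Conv2d(c2, c3, rng, stride=2), nnet.ReLU(),
            nnet.GlobalAvgPool2d(),
        ])
        self.head = nnet.Dense(c3, len(self.classes), rng, init="glorot")
        self.net = nnet.Sequential([self.body, self.head])

    # -- inference -------------------------------------------------------
    def _forward_eval(self, images, batch=128):
        x = preprocess(images, self.spec.input_size)
        fc, logits = [], []
        for i in range(0, len(x), batch):
            h = self.body.forward(x[i:i + batch])
            fc.append(h)
            logits.append(self.head.forward(h))
        return np.concatenate(fc), np.concatenate(logits)

    def logits(self, images):
        return self._forward_eval(images)[1]

    def predict_proba(self, images):
        return nnet.softmax(self.logits(images))

    def fc_features(self, images):
        return self._forward_eval(images)[0]

    def predict(self, images):
        idx = np.argmax(self.logits(images), axis=1)
        return [self.classes[i] for i in idx]


def train_backbone(images, labels, spec: BackboneSpec,
                   train_ids=None) -> BackboneModel:
    """Train the reference backbone on the (patient-grouped) training ids.

    ``images`` may be CohortImage objects (then ``labels`` defaults to
    their labels and ``train_ids`` are image ids) or raw arrays (then
    ``train_ids`` are positional indices).
    """
    images = list(images)
    if labels is None:
        labels = [im.label for im in images]
    labels = list(labels)
    if len(labels) != len(images):
        raise ValueError("labels length must match images")
    if train_ids is not None:
        if hasattr(images[0], "image_id"):
            by_id = {im.image_id: i for i, im in enumerate(images)}
            missing = [t for t in train_ids if t not in by_id]
            if missing:
                raise ValueError(f"train ids not in cohort: {missing[:5]}")
            sel = [by_id[t] for t in train_ids]
        else:
            sel = list(train_ids)
        images = [images[i] for i in sel]
        labels = [labels[i] for i in sel]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")

    model = BackboneModel(spec, classes)
    y = np.array([classes.index(l) for l in labels])
    x = preprocess(images, spec.input_size)
    opt = nnet.Adam(model.net.params, model.net.grads,
                    lr=spec.learning_rate)
    rng = np.random.default_rng(spec.seed + 1)
    n = len(images)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, spec.batch_size):
            idx = order[i:i + spec.batch_size]
            logits = model.net.forward(x[idx])
            loss, dlogits = nnet.softmax_cross_entropy(logits, y[idx])
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        logger.debug("backbone %s epoch %d loss %.4f", spec.name, epoch,
                     float(np.mean(losses)))
    return model


def extract_class_features(model: BackboneModel, images,
                           labels=None) -> pd.DataFrame:
    """Per-image class probabilities from the logits head.

    Columns: image_id, label, F1..FK (softmax probabilities), L1..LK
    (raw logits, retained for the direct-logits ablation), backbone.
    """
    images = list(images)
    logits = model.logits(images)
    probs = nnet.softmax(logits)
    k = probs.shape[1]
    ids = [im.image_id if hasattr(im, "image_id") else str(i)
           for i, im in enumerate(images)]
    if labels is None:
        labels = [getattr(im, "label", "") for im in images]
    df = pd.DataFrame({"image_id": ids, "label": list(labels)})
    for j in range(k):
        df[f"F{j + 1}"] = probs[:, j].astype(np.float64)
    for j in range(k):
        df[f"L{j + 1}"] = logits[:, j].astype(np.float64)
    df["backbone"] = model.spec.name
    return df


def extract_fc_features(model: BackboneModel, images) -> pd.DataFrame:
    """Penultimate (pre-logits) representation, one fixed-width row per
    image; width equals the backbone's declared ``fc_width``."""
    images = list(images)
    fc = model.fc_features(images)
    ids = [im.image_id if hasattr(im, "image_id") else str(i)
           for i, im in enumerate(images)]
    df = pd.DataFrame(fc, columns=[f"fc{j}" for j in range(fc.shape[1])])
    df.insert(0, "image_id", ids)
    return df


def feature_columns(df: pd.DataFrame, kind="prob"):
    """Names of the F (softmax) or L (raw logits) columns, in order."""
    prefix = {"prob": "F", "logit": "L"}[kind]
    cols = [c for c in df.columns
            if c.startswith(prefix) and c[len(prefix):].isdigit()]
    return sorted(cols, key=lambda c: int(c[len(prefix):]))
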