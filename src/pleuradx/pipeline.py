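"""End-to-end pipeline orchestration and the ablation grid.

The three-step pipeline: (1) segment every slice and composite the
masks over the source with >= 50% transparency; (2) train the image
backbone on the patient-grouped training split and extract class-based
(logits-layer) features for every slice; (3) render each feature vector
into decoder/GAN/NeRV candidate images, select the best representative
per sample by discriminative score, and classify the selected images
with the residual-feature SVM.  Evaluation runs under a patient-grouped
holdout (70/30) and k-fold cross-validation.

A single global seed fans out to per-stage derived seeds (stage name
hashed), so any stage can be re-run independently and the whole run is
reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifiers, cohort, evaluation, rendering, segmentation
from . import selection as sel
from .backbone import (BackboneSpec, extract_class_features, feature_columns,
                       train_backbone)
from .cohort import LABEL_POS, CohortConfig

logger = logging.getLogger(__name__)

SELECTION_MODES = ("ds", "variance")
CLASSIFIER_MODES = ("residual_svm", "logreg", "direct_logits")
SCHEMES = ("holdout", "kfold")

#: Ablation grid scenarios: (name, selection mode, classifier mode).
ABLATION_SCENARIOS = (
    ("full", "ds", "residual_svm"),
    ("no_rendering", "ds", "direct_logits"),
    ("variance_selector", "variance", "residual_svm"),
    ("logistic_regression", "ds", "logreg"),
)


class PipelineStageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one (stage-name hashed)."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RendererSettings:
    size: int = 32
    decoder_epochs: int = 150
    gan_epochs: int = 100
    nerv_epochs: int = 150
    learning_rate: float = 1e-3


@dataclass
class SplitSettings:
    holdout_ratio: float = 0.7
    k: int = 5
    schemes: tuple = ("holdout", "kfold")


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None
    backbone: BackboneSpec = field(default_factory=lambda: BackboneSpec(
        learning_rate=1e-3, epochs=8))
    renderer: RendererSettings = field(default_factory=RendererSettings)
    split: SplitSettings = field(default_factory=SplitSettings)
    selection_mode: str = "ds"
    classifier_mode: str = "residual_svm"
    residual_epochs: int = 6
    min_mask_area: int = 50
    overlay_alpha: float = 0.5
    bootstrap: int = 200
    seed: int = 42
    out_dir: str | None = None

    def __post_init__(self):
        if self.selection_mode not in SELECTION_MODES:
            raise ValueError(f"selection_mode must be one of "
                             f"{SELECTION_MODES}")
        if self.classifier_mode not in CLASSIFIER_MODES:
            raise ValueError(f"classifier_mode must be one of "
                             f"{CLASSIFIER_MODES}")
        for s in self.split.schemes:
            if s not in SCHEMES:
                raise ValueError(f"unknown scheme {s!r}")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ValueError(f"input_dir does not exist: {self.input_dir}")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("schema_version", None)
        kwargs = dict(raw)
        if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
            kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
        if "backbone" in kwargs and isinstance(kwargs["backbone"], dict):
            spec = kwargs["backbone"]
            spec["channels"] = tuple(spec.get("channels", (16, 32, 64)))
            kwargs["backbone"] = BackboneSpec(**spec)
        if "renderer" in kwargs and isinstance(kwargs["renderer"], dict):
            kwargs["renderer"] = RendererSettings(**kwargs["renderer"])
        if "split" in kwargs and isinstance(kwargs["split"], dict):
            s = kwargs["split"]
            s["schemes"] = tuple(s.get("schemes", ("holdout", "kfold")))
            kwargs["split"] = SplitSettings(**s)
        return cls(**kwargs)

    def to_yaml(self, path):
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, tuple):
                return list(o)
            return o
        doc = {"schema_version": 1}
        doc.update({k: enc(v) for k, v in dataclasses.asdict(self).items()})
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class RunResult:
    reports: dict                 # scheme -> MetricReport
    manifest: dict
    cohort_table: pd.DataFrame
    selection_rows: dict = field(default_factory=dict)


def _sha(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _prepare(config: PipelineConfig):
    """Cohort generation/loading plus segmentation overlays."""
    t0 = time.perf_counter()
    if config.input_dir is not None:
        images = cohort.read_cohort(config.input_dir)
    else:
        cc = dataclasses.replace(config.cohort,
                                 seed=stage_seed(config.seed, "cohort"))
        images, _ = cohort.generate_cohort(cc)
    table = pd.DataFrame([(im.image_id, im.patient_id, im.label)
                          for im in images],
                         columns=["image_id", "patient_id", "label"])
    provider = segmentation.ToySegmenter(config.min_mask_area)
    masksets = segmentation.apply_mask_provider(provider, images)
    spec = segmentation.OverlaySpec(alpha=config.overlay_alpha)
    overlays = segmentation.overlay_batch(images, masksets, spec)
    logger.info("prepared %d slices in %.1fs", len(images),
                time.perf_counter() - t0)
    return {"images": images, "table": table, "overlays": overlays}


class _OverlayView:
    """Adapter giving overlay arrays the image_id/label of their slice."""

    def __init__(self, image_id, label, pixels):
        self.image_id, self.label, self.pixels = image_id, label, pixels


def _shared_stages(prep, train_ids, config, want_renders=True):
    """Backbone + features (+ renderers and candidate renders), computed
    once per training split and shared across ablation scenarios."""
    views = [_OverlayView(im.image_id, im.label, ov)
             for im, ov in zip(prep["images"], prep["overlays"])]
    spec = dataclasses.replace(config.backbone,
                               seed=stage_seed(config.seed, "backbone"))
    try:
        model = train_backbone(views, None, spec, train_ids=train_ids)
        features = extract_class_features(model, views)
    except Exception as exc:
        raise PipelineStageError("backbone_features", exc) from exc
    out = {"backbone": model, "features": features}
    if want_renders:
        try:
            train_feat = features[features["image_id"].isin(train_ids)]
            r = config.renderer
            renderers = {
                "decoder": rendering.train_decoder_renderer(
                    train_feat, r.size, r.size,
                    seed=stage_seed(config.seed, "decoder"),
                    epochs=r.decoder_epochs, lr=r.learning_rate),
                "gan": rendering.train_gan_renderer(
                    train_feat, r.size, r.size,
                    seed=stage_seed(config.seed, "gan"),
                    epochs=r.gan_epochs, lr=r.learning_rate),
                "nerv": rendering.train_nerv_renderer(
                    train_feat, r.size, r.size,
                    seed=stage_seed(config.seed, "nerv"),
                    epochs=r.nerv_epochs, lr=r.learning_rate),
            }
            candidates = rendering.render_all(features, renderers,
                                              r.size, r.size)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("generative_rendering", exc) from exc
        out["renderers"] = renderers
        out["candidates"] = candidates
    return out


def _classify_split(shared, train_ids, test_ids, selection_mode,
                    classifier_mode, config):
    """Selection + classification for one train/test split; returns
    (y_true, y_pred, positive-class scores, manifest rows or None)."""
    features = shared["features"]
    test_mask = features["image_id"].isin(test_ids)
    train_mask = features["image_id"].isin(train_ids)
    y_true = list(features.loc[test_mask, "label"])
    seed = stage_seed(config.seed, "classifier")

    if classifier_mode == "direct_logits":
        try:
            model = classifiers.classify_direct_logits(
                features[train_mask], spec=classifiers.SvmSpec(seed=seed))
            cols = model.feature_columns
            x_test = features.loc[test_mask, cols].to_numpy(float)
            y_pred = list(model.predict(x_test))
            proba = model.predict_proba(x_test)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("residual_svm", exc) from exc
        pos_idx = model.classes_.index(LABEL_POS)
        return y_true, y_pred, proba[:, pos_idx], None

    # selection + residual features depend only on the selection mode for
    # a fixed split, so cache them across ablation scenarios
    cache = shared.setdefault("_selection_cache", {})
    if selection_mode not in cache:
        candidates = shared["candidates"]
        try:
            if selection_mode == "ds":
                centroids = sel.fit_centroids(candidates, fit_ids=train_ids)
                rows = sel.select_representatives(candidates, centroids)
            else:
                rows = sel.variance_select(candidates)
            images = sel.selected_images(candidates, rows)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("discriminative_selection", exc) from exc

        ids = list(features["image_id"])
        labels = list(features["label"])
        tr_idx = [i for i, iid in enumerate(ids) if iid in set(train_ids)]
        te_idx = [i for i, iid in enumerate(ids) if iid in set(test_ids)]
        try:
            extractor = classifiers.ResidualFeatureExtractor(
                input_size=config.renderer.size,
                seed=stage_seed(config.seed, "residual"))
            extractor.fit([images[i] for i in tr_idx],
                          [labels[i] for i in tr_idx],
                          epochs=config.residual_epochs)
            cache[selection_mode] = {
                "rows": rows,
                "x_train": extractor.transform([images[i] for i in tr_idx]),
                "x_test": extractor.transform([images[i] for i in te_idx]),
                "y_train": [labels[i] for i in tr_idx],
            }
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("residual_svm", exc) from exc
    cached = cache[selection_mode]
    rows = cached["rows"]
    x_train, x_test = cached["x_train"], cached["x_test"]
    y_train = cached["y_train"]
    try:
        if classifier_mode == "residual_svm":
            model = classifiers.train_svm(x_train, y_train,
                                          classifiers.SvmSpec(seed=seed))
        else:
            model = classifiers.train_logreg(x_train, y_train, seed=seed)
        y_pred = list(model.predict(x_test))
        proba = model.predict_proba(x_test)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("residual_svm", exc) from exc
    pos_idx = model.classes_.index(LABEL_POS)
    return y_true, y_pred, proba[:, pos_idx], rows


def _evaluate(y_true, y_pred, scores, config, per_fold=None):
    rep = evaluation.evaluate_predictions(
        y_true, y_pred, scores=scores, probs=scores,
        positive_label=LABEL_POS, bootstrap=config.bootstrap,
        seed=stage_seed(config.seed, "bootstrap"))
    if per_fold:
        rep.per_fold = per_fold
    return rep


def _run_scheme(prep, config, scheme, selection_mode, classifier_mode,
                shared_cache):
    want_renders = classifier_mode != "direct_logits"
    if scheme == "holdout":
        plan = evaluation.grouped_split(
            prep["table"], "holdout", config.split.holdout_ratio,
            seed=stage_seed(config.seed, "split_holdout"))
        evaluation.check_no_leakage(plan, prep["table"])
        key = ("holdout", tuple(plan.train_ids))
        shared = shared_cache.get(key)
        if shared is None or (want_renders and "candidates" not in shared):
            shared = _shared_stages(prep, plan.train_ids, config,
                                    want_renders=want_renders)
            shared_cache[key] = shared
        y_true, y_pred, scores, rows = _classify_split(
            shared, plan.train_ids, plan.test_ids, selection_mode,
            classifier_mode, config)
        return _evaluate(y_true, y_pred, scores, config), rows

    # kfold: retrain everything inside each fold, pool the predictions
    plan = evaluation.grouped_split(
        prep["table"], "kfold", config.split.k,
        seed=stage_seed(config.seed, "split_kfold"))
    evaluation.check_no_leakage(plan, prep["table"])
    all_t, all_p, all_s = [], [], []
    per_fold = []
    rows_last = None
    for f, (train_ids, test_ids) in enumerate(plan.folds):
        key = ("fold", f, tuple(train_ids))
        if key not in shared_cache or (
                want_renders and "candidates" not in shared_cache[key]):
            shared_cache[key] = _shared_stages(prep, train_ids, config,
                                               want_renders=want_renders)
        y_true, y_pred, scores, rows_last = _classify_split(
            shared_cache[key], train_ids, test_ids, selection_mode,
            classifier_mode, config)
        classes = sorted(set(y_true) | set(y_pred))
        cms = {c: evaluation.confusion(y_true, y_pred, c) for c in classes}
        per_fold.append(evaluation.macro_metrics(cms))
        all_t.extend(y_true)
        all_p.extend(y_pred)
        all_s.extend(scores)
    return _evaluate(all_t, all_p, np.asarray(all_s), config,
                     per_fold=per_fold), rows_last


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute segment -> train -> extract -> render -> select -> classify
    -> evaluate under every configured scheme."""
    t0 = time.perf_counter()
    try:
        prep = _prepare(config)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("prepare", exc) from exc
    shared_cache: dict = {}
    reports, rows_by_scheme = {}, {}
    for scheme in config.split.schemes:
        rep, rows = _run_scheme(prep, config, scheme, config.selection_mode,
                                config.classifier_mode, shared_cache)
        reports[scheme] = rep
        if rows is not None:
            rows_by_scheme[scheme] = rows
    manifest = _build_manifest(config, prep, reports, t0)
    result = RunResult(reports=reports, manifest=manifest,
                       cohort_table=prep["table"],
                       selection_rows=rows_by_scheme)
    if config.out_dir:
        _persist(config, prep, result)
    return result


def run_ablation_grid(config: PipelineConfig) -> pd.DataFrame:
    """Run the four ablation scenarios under every configured scheme,
    sharing the backbone/rendering stages within each split.

    Returns one row per scenario x scheme with the macro metrics.
    """
    prep = _prepare(config)
    shared_cache: dict = {}
    rows = []
    for scenario, selection_mode, classifier_mode in ABLATION_SCENARIOS:
        for scheme in config.split.schemes:
            rep, _ = _run_scheme(prep, config, scheme, selection_mode,
                                 classifier_mode, shared_cache)
            rows.append({
                "scenario": scenario, "scheme": scheme,
                "selection_mode": selection_mode,
                "classifier_mode": classifier_mode,
                **{m: rep.macro[m] for m in
                   ("se", "sp", "pre", "f_scr", "acc")},
                "auc": rep.auc,
            })
            logger.info("ablation %s/%s acc=%.4f", scenario, scheme,
                        rep.macro["acc"])
    df = pd.DataFrame(rows)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "ablation_grid.csv", index=False)
    return df


def _build_manifest(config, prep, reports, t0):
    stages = ["cohort", "backbone", "decoder", "gan", "nerv", "residual",
              "classifier", "split_holdout", "split_kfold", "bootstrap"]
    return {
        "config_seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in stages},
        "n_images": len(prep["images"]),
        "n_patients": int(prep["table"]["patient_id"].nunique()),
        "cohort_hash": _sha(np.stack([im.pixels for im in prep["images"]])),
        "accuracy": {scheme: rep.macro["acc"]
                     for scheme, rep in reports.items()},
        "elapsed_s": round(time.perf_counter() - t0, 2),
    }


def _persist(config, prep, result: RunResult):
    out = Path(config.out_dir)
    for sub in ("cohort", "reports", "selected"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    prep["table"].to_csv(out / "cohort" / "cohort.csv", index=False)
    for scheme, rep in result.reports.items():
        with open(out / "reports" / f"report_{scheme}.json", "w") as fh:
            json.dump(rep.to_dict(), fh, indent=1, default=float)
    for scheme, rows in result.selection_rows.items():
        sel.write_manifest(rows, out / "selected"
                           / f"manifest_{scheme}.csv")
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1)
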