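"""Discriminative-score selection of the best rendered candidate.

For every sample, three candidate images (decoder / gan / nerv) compete;
the discriminative score of a flattened candidate m is

    DS(m) = d(m, C_neg) / d(m, C_pos)

with d the Euclidean distance, C_pos the centroid of the sample's own
class and C_neg the rival class centroid.  A good representative sits
close to its own class center and far from the rival one, so selection
takes the candidate with the *highest* ratio (the reverse orientation
is available behind a flag).  Centroids are fitted on training-split
candidates only (all three renderers pooled), then applied everywhere,
so the selection step never sees test statistics.

A label-blind variance-threshold selector (pick the candidate with the
highest pixel variance) is provided as the ablation alternative, and the
selection outcome is persisted as a four-column CSV manifest
(Index,Selected_Method,Label,Image_Path).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .rendering import RENDERER_KINDS

MANIFEST_HEADER = ["Index", "Selected_Method", "Label", "Image_Path"]
_EPS = 1e-12


@dataclass
class ClassCentroids:
    centroids: dict          # label -> flattened mean vector
    fit_ids: tuple = ()

    def __post_init__(self):
        dims = {v.shape for v in self.centroids.values()}
        if len(dims) > 1:
            raise ValueError("centroid dimensionalities differ")


@dataclass
class SelectionManifestRow:
    index: int
    selected_method: str
    label: str
    image_path: str = ""

    def __post_init__(self):
        if self.selected_method not in RENDERER_KINDS:
            raise ValueError(
                f"selected_method must be one of {RENDERER_KINDS}, "
                f"got {self.selected_method!r}")


def _flat(img):
    return np.asarray(img, dtype=np.float64).ravel()


def fit_centroids(candidates, labels=None, fit_ids=None) -> ClassCentroids:
    """Per-class mean of all flattened candidate images (all renderers
    pooled) over the fitting subset.

    ``fit_ids``, when given, restricts fitting to those sample ids (the
    training split).  Raises if any class ends up unrepresented.
    """
    candidates = list(candidates)
    if labels is None:
        labels = [c.label for c in candidates]
    labels = list(labels)
    if fit_ids is not None:
        fit_ids = set(fit_ids)
        keep = [i for i, c in enumerate(candidates)
                if c.sample_id in fit_ids]
        candidates = [candidates[i] for i in keep]
        labels = [labels[i] for i in keep]
    sums, counts = {}, {}
    for cand, lab in zip(candidates, labels):
        for kind in RENDERER_KINDS:
            v = _flat(cand.images[kind])
            if lab not in sums:
                sums[lab] = np.zeros_like(v)
                counts[lab] = 0
            sums[lab] += v
            counts[lab] += 1
    if len(sums) < 2:
        raise ValueError(
            f"centroid fitting needs both classes represented, got "
            f"{sorted(sums)}")
    return ClassCentroids(
        centroids={lab: sums[lab] / counts[lab] for lab in sums},
        fit_ids=tuple(sorted(fit_ids)) if fit_ids is not None else ())


def discriminative_score(m, c_pos, c_neg) -> float:
    """DS = d(m, C_neg) / d(m, C_pos), Euclidean.

    When m coincides with C_pos (distance below 1e-12) the score is the
    capped sentinel d(m, C_neg) / 1e-12.
    """
    m, c_pos, c_neg = _flat(m), _flat(c_pos), _flat(c_neg)
    if not m.shape == c_pos.shape == c_neg.shape:
        raise ValueError("dimension mismatch between sample and centroids")
    d_pos = float(np.linalg.norm(m - c_pos))
    d_neg = float(np.linalg.norm(m - c_neg))
    if d_pos < _EPS:
        return d_neg / _EPS
    return d_neg / d_pos


def select_representatives(candidates, centroids: ClassCentroids,
                           labels=None, orientation="max",
                           paths=None) -> list:
    """Pick the best of the three candidates per sample by DS.

    ``orientation="max"`` selects the candidate with the highest
    d_neg/d_pos ratio (own-class proximity, rival-class distance);
    ``"min"`` selects the lowest.  Ties break in the fixed order
    decoder -> gan -> nerv.  ``paths`` (optional, aligned with
    ``candidates``) maps kind -> image path for the manifest.
    """
    if orientation not in ("max", "min"):
        raise ValueError("orientation must be 'max' or 'min'")
    candidates = list(candidates)
    if labels is None:
        labels = [c.label for c in candidates]
    labels = list(labels)
    class_set = sorted(centroids.centroids)
    rows = []
    for i, (cand, lab) in enumerate(zip(candidates, labels)):
        if set(cand.images) != set(RENDERER_KINDS):
            raise ValueError(
                f"sample {cand.sample_id}: expected candidates "
                f"{RENDERER_KINDS}, got {sorted(cand.images)}")
        if lab not in centroids.centroids:
            raise ValueError(f"no centroid fitted for label {lab!r}")
        c_pos = centroids.centroids[lab]
        rivals = [c for c in class_set if c != lab]
        # binary case: the single other class; K>2: nearest rival per candidate
        best_kind, best_score = None, None
        for kind in RENDERER_KINDS:  # fixed tie-break order
            m = _flat(cand.images[kind])
            # C_neg is the *nearest* rival class; for the binary problem
            # that is simply the other class, so take the smallest ratio
            d_negs = [discriminative_score(m, c_pos,
                                           centroids.centroids[r])
                      for r in rivals]
            score = min(d_negs)
            better = (best_score is None
                      or (orientation == "max" and score > best_score)
                      or (orientation == "min" and score < best_score))
            if better:
                best_kind, best_score = kind, score
        path = paths[i].get(best_kind, "") if paths else ""
        rows.append(SelectionManifestRow(index=i, selected_method=best_kind,
                                         label=lab, image_path=path))
    return rows


def variance_select(candidates, paths=None) -> list:
    """Label-blind alternative: per sample, pick the candidate with the
    highest pixel variance (same decoder -> gan -> nerv tie rule)."""
    rows = []
    for i, cand in enumerate(list(candidates)):
        if set(cand.images) != set(RENDERER_KINDS):
            raise ValueError(
                f"sample {cand.sample_id}: expected candidates "
                f"{RENDERER_KINDS}, got {sorted(cand.images)}")
        best_kind, best_var = None, None
        for kind in RENDERER_KINDS:
            v = float(np.var(_flat(cand.images[kind])))
            if best_var is None or v > best_var:
                best_kind, best_var = kind, v
        path = paths[i].get(best_kind, "") if paths else ""
        rows.append(SelectionManifestRow(index=i, selected_method=best_kind,
                                         label=cand.label, image_path=path))
    return rows


def selected_images(candidates, rows):
    """Materialize the selected image per manifest row, order preserved."""
    candidates = list(candidates)
    return [np.asarray(candidates[r.index].images[r.selected_method])
            for r in rows]


def write_manifest(rows, path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MANIFEST_HEADER)
        for r in rows:
            w.writerow([r.index, r.selected_method, r.label, r.image_path])


def read_manifest(path):
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != MANIFEST_HEADER:
            raise ValueError(
                f"manifest header mismatch: expected {MANIFEST_HEADER}, "
                f"got {header}")
        for lineno, rec in enumerate(reader, start=2):
            if len(rec) != 4:
                raise ValueError(f"malformed manifest row at line {lineno}: "
                                 f"{rec}")
            try:
                idx = int(rec[0])
            except ValueError as exc:
                raise ValueError(f"bad index at line {lineno}: {rec[0]!r}") \
                    from exc
            rows.append(SelectionManifestRow(index=idx,
                                             selected_method=rec[1],
                                             label=rec[2],
                                             image_path=rec[3]))
    return rows
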