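"""Synthetic two-class CT-phantom cohort.

Real chest-CT cohorts for pleural mesothelioma are small, single-center
and rarely public, so the pipeline is exercised on a seeded phantom
cohort that reproduces the *structure* of such a dataset: two balanced
classes, a handful of axial slices per patient, patient-grouped labels,
and a class-dependent pleural signal.

Each phantom slice is an elliptical thorax (bright body, two dark lung
fields) with a bright pleural rim around each lung.  The diseased class
carries a thicker rim (baseline + ``class_effect`` pixels, with
per-patient jitter) plus one to three nodular bumps protruding into the
lung — the CT correlate of pleural thickening with nodularity.  The
healthy class keeps the baseline rim.  Additive Gaussian noise is
applied last.  All randomness flows from a single integer seed.

Demographics (sex, age, stage, histology, asbestos exposure, smoking,
chest pain, weight loss) are sampled from fixed marginal frequencies of
a 172-patient reference cohort, and :func:`summarize_cohort` reproduces
the count/percentage arithmetic of a clinical "Table 1".
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

LABEL_POS = "mesothelioma"
LABEL_NEG = "non_mesothelioma"

# phantom intensity levels (8-bit)
INTENSITY_BACKGROUND = 5.0
INTENSITY_BODY = 170.0
INTENSITY_LUNG = 30.0
INTENSITY_RIM = 230.0

#: Marginal counts of the 172-patient reference cohort used both as
#: sampling weights and as the fixture for the summary arithmetic.
REFERENCE_N_PATIENTS = 172
REFERENCE_MARGINALS = {
    "sex": {"male": 98, "female": 74},
    "stage": {1: 15, 2: 42, 3: 68, 4: 47},
    "histology": {"epithelioid": 133, "biphasic": 16,
                  "sarcomatoid": 15, "not_determined": 8},
    "asbestos": {False: 41, True: 131},
    "smoking": {False: 75, True: 97},
    "pain": {False: 70, True: 102},
    "weight_loss": {False: 57, True: 115},
}
REFERENCE_AGE_MEAN = 56.8
REFERENCE_AGE_SD = 14.6


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``class_effect`` is the extra pleural-rim thickness (pixels) of the
    diseased class; ``slices_mean`` is the expected number of CT slices
    per patient (Poisson, clipped to [1, 12]).  ``total_per_class``, when
    set, repairs the sampled slice counts so each class contributes
    exactly that many images.
    """

    n_patients_per_class: int = 86
    slices_mean: float = 5.8
    image_size: int = 128
    class_effect: float = 4.0
    noise_sd: float = 8.0
    seed: int = 42
    rim_base: float = 3.0
    slices_max: int = 12
    total_per_class: int | None = None

    def __post_init__(self):
        if self.n_patients_per_class < 1:
            raise ValueError("n_patients_per_class must be >= 1")
        if self.slices_mean <= 0:
            raise ValueError("slices_mean must be > 0")
        if self.class_effect < 0:
            raise ValueError("class_effect must be >= 0")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CohortImage:
    image_id: str
    patient_id: str
    label: str
    pixels: np.ndarray  # uint8, H x W


@dataclass
class DemographicRecord:
    patient_id: str
    sex: str
    age: float
    stage: int
    histology: str
    asbestos: bool
    smoking: bool
    pain: bool
    weight_loss: bool


@dataclass
class DemographicSummary:
    n_patients: int
    #: field -> category -> (count, percentage rounded to one decimal)
    tables: dict = field(default_factory=dict)

    def percentage(self, field_name, category):
        return self.tables[field_name][category][1]


def _ellipse_mask(size, center, semi_axes):
    # pixel centers at integer+0.5 so the phantom is symmetric under
    # 180-degree rotation about the geometric image center
    rr, cc = np.meshgrid(np.arange(size) + 0.5, np.arange(size) + 0.5,
                         indexing="ij")
    return (((rr - center[0]) / semi_axes[0]) ** 2
            + ((cc - center[1]) / semi_axes[1]) ** 2) <= 1.0


def _render_slice(size, rim_thickness, nodules, rng, noise_sd):
    """Draw one thorax phantom slice; `nodules` is a list of (angle, radius)."""
    img = np.full((size, size), INTENSITY_BACKGROUND, dtype=np.float64)
    body = _ellipse_mask(size, (size * 0.5, size * 0.5),
                         (size * 0.38, size * 0.46))
    img[body] = INTENSITY_BODY
    lung_axes = (size * 0.24, size * 0.15)
    for lung_c in (size * 0.30, size * 0.70):
        center = (size * 0.5, lung_c)
        outer = _ellipse_mask(size, center,
                              (lung_axes[0] + rim_thickness,
                               lung_axes[1] + rim_thickness))
        inner = _ellipse_mask(size, center, lung_axes)
        img[outer & body] = INTENSITY_RIM
        img[inner] = INTENSITY_LUNG
    # nodular bumps protruding from the rim into the lung field
    for side, angle, radius in nodules:
        lung_c = size * 0.30 if side == 0 else size * 0.70
        cr = size * 0.5 + lung_axes[0] * np.sin(angle)
        cc = lung_c + lung_axes[1] * np.cos(angle)
        bump = _ellipse_mask(size, (cr, cc), (radius, radius))
        img[bump] = INTENSITY_RIM
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _slice_counts(rng, n_patients, mean, clip_max, total=None):
    counts = np.clip(rng.poisson(mean, size=n_patients), 1, clip_max)
    if total is not None:
        if not n_patients <= total <= n_patients * clip_max:
            raise ValueError("total_per_class incompatible with patient count")
        while counts.sum() != total:
            i = rng.integers(n_patients)
            if counts.sum() < total and counts[i] < clip_max:
                counts[i] += 1
            elif counts.sum() > total and counts[i] > 1:
                counts[i] -= 1
    return counts


def generate_cohort(config: CohortConfig):
    """Generate the phantom cohort.

    Returns ``(images, records)``: one :class:`CohortImage` per slice and
    one :class:`DemographicRecord` per patient.  Fully deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    images: list[CohortImage] = []
    patient_ids = []
    labels = []
    for cls_idx, label in enumerate((LABEL_POS, LABEL_NEG)):
        counts = _slice_counts(rng, config.n_patients_per_class,
                               config.slices_mean, config.slices_max,
                               config.total_per_class)
        for p in range(config.n_patients_per_class):
            pid = f"P{cls_idx}{p:03d}"
            patient_ids.append(pid)
            labels.append(label)
            if label == LABEL_POS:
                jitter = rng.normal(0.0, 0.8)
                rim = max(1.0, config.rim_base + config.class_effect + jitter)
                n_nod = rng.integers(1, 4) if config.class_effect > 0 else 0
            else:
                jitter = rng.normal(0.0, 0.8) * (0.5 if config.class_effect > 0
                                                 else 1.0)
                rim = max(1.0, config.rim_base + jitter)
                n_nod = 0
            nodules = [(int(rng.integers(2)),
                        rng.uniform(0, 2 * np.pi),
                        rng.uniform(2.0, 4.0) * (1 + 0.3 * config.class_effect
                                                 / 4.0))
                       for _ in range(n_nod)]
            for s in range(counts[p]):
                slice_rim = max(1.0, rim + rng.normal(0.0, 0.3))
                pix = _render_slice(config.image_size, slice_rim, nodules,
                                    rng, config.noise_sd)
                images.append(CohortImage(
                    image_id=f"{pid}_s{s}", patient_id=pid, label=label,
                    pixels=pix))
    records = sample_demographics(len(patient_ids), seed=config.seed + 1)
    for rec, pid in zip(records, patient_ids):
        rec.patient_id = pid
    return images, records


def sample_demographics(n_patients: int, seed: int):
    """Sample patient records from the reference marginal frequencies."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_patients):
        rec = {"patient_id": f"P{i:04d}"}
        for fname, cats in REFERENCE_MARGINALS.items():
            keys = list(cats)
            probs = np.array([cats[k] for k in keys], dtype=float)
            probs /= probs.sum()
            rec[fname] = keys[rng.choice(len(keys), p=probs)]
        age = rng.normal(REFERENCE_AGE_MEAN, REFERENCE_AGE_SD)
        rec["age"] = float(np.clip(age, 20.0, 95.0))
        records.append(DemographicRecord(**rec))
    return records


def make_reference_records():
    """Build 172 records whose marginal counts equal the reference table
    exactly (fields assigned independently, in deterministic order)."""
    n = REFERENCE_N_PATIENTS
    columns = {}
    for fname, cats in REFERENCE_MARGINALS.items():
        col = []
        for cat, count in cats.items():
            col.extend([cat] * count)
        assert len(col) == n
        columns[fname] = col
    return [DemographicRecord(patient_id=f"R{i:03d}", age=REFERENCE_AGE_MEAN,
                              **{f: columns[f][i] for f in columns})
            for i in range(n)]


def summarize_cohort(records) -> DemographicSummary:
    """Count/percentage summary per categorical field; percentages are of
    the total patient count, rounded to one decimal place."""
    records = list(records)
    if not records:
        raise ValueError("cannot summarize an empty record list")
    n = len(records)
    tables = {}
    for fname in REFERENCE_MARGINALS:
        counts = {}
        for rec in records:
            v = getattr(rec, fname)
            counts[v] = counts.get(v, 0) + 1
        tables[fname] = {cat: (cnt, round(100.0 * cnt / n, 1))
                         for cat, cnt in counts.items()}
    return DemographicSummary(n_patients=n, tables=tables)


def estimate_rim_area(image: np.ndarray) -> int:
    """Pixels in the brightest intensity class (the pleural rim) of a
    phantom slice, via a three-level multi-Otsu threshold."""
    from skimage.filters import threshold_multiotsu

    th = threshold_multiotsu(image, classes=3)
    return int(np.count_nonzero(image > th[-1]))


# ---------------------------------------------------------------------------
# disk I/O


def write_cohort(images, records, out_dir):
    """Persist slices as 8-bit grayscale PNG plus the two CSV tables."""
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    with open(out / "cohort.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "patient_id", "label"])
        for im in images:
            Image.fromarray(im.pixels, mode="L").save(
                img_dir / f"{im.image_id}.png")
            w.writerow([im.image_id, im.patient_id, im.label])
    with open(out / "demographics.csv", "w", newline="") as fh:
        fields = [f.name for f in dataclasses.fields(DemographicRecord)]
        w = csv.writer(fh)
        w.writerow(fields)
        for rec in records:
            w.writerow([getattr(rec, f) for f in fields])


def read_cohort(in_dir):
    """Load a cohort previously written by :func:`write_cohort`."""
    root = Path(in_dir)
    images = []
    with open(root / "cohort.csv", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            pix = np.asarray(Image.open(root / "images"
                                        / f"{row['image_id']}.png"))
            images.append(CohortImage(row["image_id"], row["patient_id"],
                                      row["label"], pix))
    return images
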