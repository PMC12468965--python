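"""Region segmentation and transparent overlay compositing.

The pipeline's first stage obtains region masks from a pluggable
provider and composites them over the source slice with at least 50%
transparency, so the segmented region and the underlying tissue stay
simultaneously visible.  A foundation segmenter (e.g. a pretrained
promptable model) can be plugged in through the :class:`MaskProvider`
contract; the testable default is a deterministic Otsu +
connected-components segmenter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

logger = logging.getLogger(__name__)

#: Default palette cycled across masks (RGB), chosen for contrast.
DEFAULT_PALETTE = (
    (255, 0, 0), (0, 160, 255), (0, 200, 0), (255, 200, 0),
    (200, 0, 255), (0, 255, 200),
)


@dataclass
class MaskSet:
    """Binary region masks for one image, largest first."""

    masks: list = field(default_factory=list)  # uint8 {0,1}, H x W each
    scores: list | None = None

    def __len__(self):
        return len(self.masks)


@dataclass
class OverlaySpec:
    """Overlay opacity (<= 0.5, i.e. transparency >= 50%) and palette."""

    alpha: float = 0.5
    palette: tuple = DEFAULT_PALETTE

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 0.5:
            raise ValueError(
                f"alpha must lie in [0, 0.5] (transparency >= 50%), "
                f"got {self.alpha}")
        if not self.palette:
            raise ValueError("palette must be non-empty")


class MaskProvider:
    """Contract for pluggable segmenters: ``segment(image) -> MaskSet``."""

    def segment(self, image: np.ndarray) -> MaskSet:  # pragma: no cover
        raise NotImplementedError


def toy_segment(image: np.ndarray, min_area: int = 50) -> MaskSet:
    """Otsu threshold -> 8-connected components -> area filter.

    Components with area >= ``min_area`` are returned largest-first.
    A blank (constant) image yields an empty :class:`MaskSet`.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("toy_segment expects a 2-D grayscale image")
    if image.min() == image.max():
        return MaskSet()
    fg = image > threshold_otsu(image)
    labeled, n = cc_label(fg, connectivity=2, return_num=True)
    comps = []
    for i in range(1, n + 1):
        m = labeled == i
        area = int(m.sum())
        if area >= min_area:
            comps.append((area, m.astype(np.uint8)))
    comps.sort(key=lambda t: -t[0])
    return MaskSet(masks=[m for _, m in comps])


class ToySegmenter(MaskProvider):
    def __init__(self, min_area: int = 50):
        self.min_area = min_area

    def segment(self, image):
        return toy_segment(image, self.min_area)


def _round_half_away(x):
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def blend_overlay(image: np.ndarray, masks: MaskSet,
                  spec: OverlaySpec | None = None) -> np.ndarray:
    """Composite colored masks over a grayscale base image.

    Inside each mask the output is
    ``round(alpha * color + (1 - alpha) * base)`` (round half away from
    zero); the palette is cycled by mask index and later masks overwrite
    earlier ones where they overlap.  Pixels outside all masks are the
    base replicated to RGB.
    """
    spec = spec or OverlaySpec()
    if spec.alpha > 0.5:
        raise ValueError("alpha must be <= 0.5")
    base = np.asarray(image, dtype=np.float64)
    if base.ndim != 2:
        raise ValueError("blend_overlay expects a 2-D grayscale base")
    out = np.repeat(base[:, :, None], 3, axis=2)
    for idx, mask in enumerate(masks.masks):
        mask = np.asarray(mask)
        if mask.shape != base.shape:
            raise ValueError(
                f"mask {idx} shape {mask.shape} does not match image "
                f"shape {base.shape}")
        color = np.array(spec.palette[idx % len(spec.palette)], dtype=float)
        sel = mask.astype(bool)
        out[sel] = spec.alpha * color + (1.0 - spec.alpha) * base[sel, None]
    out = _round_half_away(out)
    return np.clip(out, 0, 255).astype(np.uint8)


def apply_mask_provider(provider, images) -> list:
    """Run a provider over a batch, order-preserving.

    A failure on an individual image is logged and yields an empty
    :class:`MaskSet`; a provider that fails on *every* image raises.
    """
    seg = provider.segment if hasattr(provider, "segment") else provider
    images = list(images)
    out = []
    failures = 0
    for i, im in enumerate(images):
        pixels = im.pixels if hasattr(im, "pixels") else im
        try:
            out.append(seg(pixels))
        except Exception as exc:  # noqa: BLE001 - contract: log and continue
            failures += 1
            logger.warning("mask provider failed on image %d: %s", i, exc)
            out.append(MaskSet())
    if images and failures == len(images):
        raise RuntimeError("mask provider failed on every image in the batch")
    return out


def overlay_batch(images, masksets, spec: OverlaySpec | None = None):
    """Blend a batch of cohort images with their mask sets."""
    return [blend_overlay(im.pixels if hasattr(im, "pixels") else im, ms, spec)
            for im, ms in zip(images, masksets)]
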