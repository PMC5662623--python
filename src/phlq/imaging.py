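"""Synthetic punctate images, ROI detection, colocalization and trace
extraction.

Boutons appear as Gaussian puncta; ROIs are 4x4-pixel boxes (0-based,
half-open) centered on detected intensity-weighted centers, following the
field's MetaMorph-style workflow.  The proprietary "auto threshold for light
objects" is replaced by a global mean + k*sd threshold (k configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .model import BoutonTrace, Protocol

ROI_SIZE = 4


class ImagingError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of a two-channel synthetic punctum field."""

    shape: tuple[int, int] = (256, 256)
    n_puncta: int = 20
    intensity_mean: float = 50.0
    intensity_sd: float = 5.0
    sigma: float = 1.8
    background: float = 100.0
    noise_sd: float = 10.0
    p_coloc: float = 1.0
    min_separation: float = 8.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_coloc <= 1.0):
            raise ImagingError("p_coloc must lie in [0, 1]")
        if self.n_puncta < 0:
            raise ImagingError("n_puncta must be >= 0")
        if self.noise_sd < 0 or self.intensity_mean < 0:
            raise ImagingError("intensities must be non-negative")


@dataclass
class RoiSet:
    """4x4-pixel boxes at detected bouton centers.

    ``boxes`` holds (row, col) top-left corners, 0-based, half-open; the
    sub-pixel intensity-weighted centers are kept alongside.
    """

    boxes: list[tuple[int, int]]
    centers: np.ndarray
    channel: int = 0
    threshold: float = float("nan")
    size: int = ROI_SIZE

    def __len__(self) -> int:
        return len(self.boxes)


def _add_spot(img: np.ndarray, cy: float, cx: float, amp: float, sigma: float) -> None:
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
    )


def render_puncta_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a two-channel punctum field.

    Returns ``(image, centers, in_channel2)``: a (2, H, W) float image,
    the (n, 2) ground-truth centers (row, col), and a boolean mask saying
    which channel-1 puncta also appear in channel 2 (independently with
    probability ``p_coloc``).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    margin = 4
    centers = []
    attempts = 0
    while len(centers) < spec.n_puncta:
        attempts += 1
        if attempts > 200 * max(spec.n_puncta, 1):
            raise ImagingError(
                "could not place puncta at the requested separation (packing limit)"
            )
        c = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.hypot(*(c - np.asarray(p))) >= spec.min_separation for p in centers):
            centers.append(tuple(c))
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)

    img = np.full((2, h, w), spec.background, dtype=float)
    in_ch2 = rng.random(len(centers)) < spec.p_coloc
    for i, (cy, cx) in enumerate(centers):
        amp1 = max(rng.normal(spec.intensity_mean, spec.intensity_sd), 0.0)
        _add_spot(img[0], cy, cx, amp1, spec.sigma)
        if in_ch2[i]:
            amp2 = max(rng.normal(spec.intensity_mean, spec.intensity_sd), 0.0)
            _add_spot(img[1], cy, cx, amp2, spec.sigma)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img, centers, in_ch2


def _box_from_center(cy: float, cx: float, shape: tuple[int, int]) -> tuple[int, int]:
    # center the 4x4 half-open box on the (sub-pixel) centroid
    top = int(round(cy - (ROI_SIZE - 1) / 2.0))
    left = int(round(cx - (ROI_SIZE - 1) / 2.0))
    top = min(max(top, 0), shape[0] - ROI_SIZE)
    left = min(max(left, 0), shape[1] - ROI_SIZE)
    return top, left


def detect_rois(
    image: np.ndarray,
    min_separation: float = 4.0,
    k: float = 3.0,
    min_area: int = 4,
    channel: int = 0,
    n_sample: Optional[int] = None,
    seed: Optional[int] = None,
) -> RoiSet:
    """Detect punctum ROIs by global thresholding.

    Pixels above mean + k*sd form connected components; components smaller
    than ``min_area`` pixels are treated as noise.  Each component is reduced
    to its intensity-weighted center (weights above the image mean); centers
    closer than ``min_separation`` are merged.  ``n_sample`` optionally
    subsamples the detected ROIs at random (seeded).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ImagingError("detect_rois expects a single-channel 2-D image")
    if not np.all(np.isfinite(image)):
        raise ImagingError("image must be finite")
    if float(image.std()) == 0.0:
        raise ImagingError("constant image: no threshold can be defined")

    thr = float(image.mean() + k * image.std())
    mask = image > thr
    labels, n_lab = ndimage.label(mask)
    if n_lab == 0:
        return RoiSet([], np.empty((0, 2)), channel, thr)

    weights = image - image.mean()
    centers = []
    for lab in range(1, n_lab + 1):
        idx = np.nonzero(labels == lab)
        if idx[0].size < min_area:
            continue
        wsum = weights[idx].sum()
        cy = float((idx[0] * weights[idx]).sum() / wsum)
        cx = float((idx[1] * weights[idx]).sum() / wsum)
        centers.append((cy, cx))

    # merge centers closer than min_separation (single-link, weighted mean)
    merged: list[list[tuple[float, float]]] = []
    for c in centers:
        for group in merged:
            if any(np.hypot(c[0] - g[0], c[1] - g[1]) < min_separation for g in group):
                group.append(c)
                break
        else:
            merged.append([c])
    final = np.asarray([np.mean(g, axis=0) for g in merged], dtype=float).reshape(-1, 2)

    if n_sample is not None and n_sample < len(final):
        rng = np.random.default_rng(seed)
        final = final[rng.choice(len(final), size=n_sample, replace=False)]

    boxes = [_box_from_center(cy, cx, image.shape) for cy, cx in final]
    return RoiSet(boxes, final, channel, thr)


def roi_means(image: np.ndarray, rois: RoiSet) -> np.ndarray:
    """Mean intensity of each 4x4 ROI box in ``image``."""
    h, w = image.shape
    out = np.empty(len(rois))
    for i, (top, left) in enumerate(rois.boxes):
        if not (0 <= top <= h - rois.size and 0 <= left <= w - rois.size):
            raise ImagingError(f"ROI {i} at ({top}, {left}) out of bounds")
        out[i] = image[top : top + rois.size, left : left + rois.size].mean()
    return out


def colocalization_pct(rois: RoiSet, other_channel: np.ndarray, k: float = 3.0) -> float:
    """Percentage of ROIs positive in the other channel.

    An ROI is positive when its 4x4 mean exceeds the other channel's
    mean + k*sd threshold scaled to the ROI mean (sd / sqrt(box area)),
    i.e. the same k-sigma rule applied at the statistic actually compared.
    """
    if len(rois) == 0:
        raise ImagingError("empty ROI set")
    other = np.asarray(other_channel, dtype=float)
    thr = other.mean() + k * other.std() / np.sqrt(rois.size**2)
    means = roi_means(other, rois)
    return 100.0 * float(np.count_nonzero(means > thr)) / len(rois)


def extract_traces(
    stack: np.ndarray, rois: RoiSet, protocol: Protocol
) -> list[BoutonTrace]:
    """Per-ROI, per-frame 4x4 mean intensities as BoutonTrace objects."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ImagingError("stack must be (frames, H, W)")
    if stack.shape[0] != protocol.n_frames:
        raise ImagingError(
            f"stack has {stack.shape[0]} frames but protocol expects {protocol.n_frames}"
        )
    h, w = stack.shape[1:]
    traces = []
    for i, (top, left) in enumerate(rois.boxes):
        if not (0 <= top <= h - rois.size and 0 <= left <= w - rois.size):
            raise ImagingError(f"ROI {i} at ({top}, {left}) out of stack bounds")
        f = stack[:, top : top + rois.size, left : left + rois.size].mean(axis=(1, 2))
        traces.append(
            BoutonTrace(protocol.times(), f, protocol, bouton_id=i)
        )
    return traces


def render_trace_stack(
    traces: Sequence[BoutonTrace],
    shape: tuple[int, int] = (96, 96),
    background: float = 20.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, RoiSet]:
    """Render simulated bouton traces into a synthetic time-lapse stack.

    Each trace occupies one uniform 4x4 block whose pixels carry the trace
    value, so the ROI mean reads the trace back exactly up to the constant
    background and noise.  Returns the stack and the ground-truth RoiSet.
    """
    if not traces:
        raise ImagingError("no traces to render")
    n_frames = len(traces[0])
    rng = np.random.default_rng(seed)
    h, w = shape
    per_row = max(1, (w - 8) // 12)
    boxes = []
    for i in range(len(traces)):
        top = 4 + 12 * (i // per_row)
        left = 4 + 12 * (i % per_row)
        if top > h - ROI_SIZE:
            raise ImagingError("too many traces for the requested stack shape")
        boxes.append((top, left))
    stack = np.full((n_frames, h, w), background, dtype=float)
    for (top, left), tr in zip(boxes, traces):
        stack[:, top : top + ROI_SIZE, left : left + ROI_SIZE] += tr.fluorescence[
            :, None, None
        ]
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
    centers = np.asarray(
        [(top + (ROI_SIZE - 1) / 2, left + (ROI_SIZE - 1) / 2) for top, left in boxes]
    )
    return stack, RoiSet(boxes, centers)
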