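"""White-pixel keyboard-use estimation from video frames.

The keyboard's white keys dominate a calibrated image region; when a hand
plays or touches the keys it occludes them and the white-pixel fraction in
that part of the region drops. The region is split into vertical partitions
(default two: left/right half of the keyboard) so the occluded part hints at
which hand is over the keys. "White" means every RGB channel is within
``white_tolerance`` of 255 (Chebyshev distance from pure white), which keeps
the classification monotone in the tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, ValidationError


@dataclass(frozen=True)
class KeyboardRegion:
    """Calibrated keyboard rectangle, half-open pixel bounds."""

    rectangle: tuple  # (x0, y0, x1, y1)
    n_partitions: int = 2
    white_tolerance: int = 60

    def __post_init__(self):
        x0, y0, x1, y1 = self.rectangle
        if x1 <= x0 or y1 <= y0:
            raise ValidationError(f"degenerate keyboard rectangle {self.rectangle}")
        if self.n_partitions < 1:
            raise ValidationError("n_partitions must be >= 1")
        if not 0 <= self.white_tolerance <= 255:
            raise ValidationError("white_tolerance must be in 0..255")


@dataclass(frozen=True)
class OcclusionSample:
    frame_index: int
    white_fraction: tuple  # per partition, in [0, 1]
    occluded: tuple  # per partition booleans


def _partition_slices(x0: int, x1: int, n: int):
    edges = np.linspace(x0, x1, n + 1).round().astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n)]


def white_fraction(image: np.ndarray, region: KeyboardRegion) -> np.ndarray:
    """Fraction of near-white pixels in each vertical partition of the region."""
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[:, :, None].repeat(3, axis=2)
    h, w = image.shape[:2]
    x0, y0, x1, y1 = region.rectangle
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValidationError(
            f"keyboard rectangle {region.rectangle} outside image bounds {(w, h)}"
        )
    patch = image[y0:y1, x0:x1, :3].astype(np.int16)
    dist = np.abs(patch - 255).max(axis=2)  # Chebyshev distance from white
    is_white = dist <= region.white_tolerance
    fractions = []
    for px0, px1 in _partition_slices(0, x1 - x0, region.n_partitions):
        part = is_white[:, px0:px1]
        fractions.append(float(part.mean()) if part.size else 0.0)
    return np.array(fractions)


def occlusion_series(
    fractions,
    baseline_quantile: float = 0.9,
    drop_fraction: float = 0.2,
    frame_indices=None,
) -> list[OcclusionSample]:
    """Flag occluded partitions from a per-frame white-fraction series.

    The per-partition baseline is the ``baseline_quantile`` of its fractions
    over the session (a high quantile, so the unoccluded level even when the
    keyboard is covered much of the time); a partition is occluded at frame t
    when its fraction drops below (1 - drop_fraction) * baseline.
    """
    fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
    n_frames, n_parts = fractions.shape
    if n_frames < 10:
        raise ValidationError(
            f"need at least 10 frames to estimate the baseline, got {n_frames}"
        )
    baselines = np.quantile(fractions, baseline_quantile, axis=0)
    if np.any(baselines <= 0):
        raise CalibrationError(
            "a partition's white-fraction baseline is zero: keyboard not found "
            "in the configured region"
        )
    occluded = fractions < (1.0 - drop_fraction) * baselines[None, :]
    if frame_indices is None:
        frame_indices = range(n_frames)
    return [
        OcclusionSample(int(f), tuple(fractions[i]), tuple(bool(b) for b in occluded[i]))
        for i, f in enumerate(frame_indices)
    ]
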