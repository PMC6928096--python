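"""Core containers: label volumes and grayscale slice stacks."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class Label(IntEnum):
    """Per-pixel region labels shared by ground truth and segmentation."""

    BACKGROUND = 0
    PERIPHERAL = 1
    CENTRAL = 2
    CAVITY = 3


LABEL_NAMES = {int(v): v.name for v in Label}

#: RGB overlay colours: peripheral blue, central red, cavity pink.
LABEL_COLORS = {
    Label.BACKGROUND: (0, 0, 0),
    Label.PERIPHERAL: (40, 80, 230),
    Label.CENTRAL: (220, 40, 40),
    Label.CAVITY: (250, 150, 210),
}


@dataclass
class LabelVolume:
    """Ordered stack of per-pixel label slices with physical spacing.

    ``data`` has shape ``(n_slices, ny, nx)`` and dtype uint8 drawn from the
    :class:`Label` alphabet.  The slicing axis is the urethra axis; pixel
    indices are 0-based and a pixel belongs to a region if its center falls
    inside the continuous boundary.
    """

    data: np.ndarray
    pixel_spacing_mm: float
    slice_spacing_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 3:
            raise ValueError("label data must be 3-D (n_slices, ny, nx)")
        if self.pixel_spacing_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("spacings must be positive")
        valid = np.isin(self.data, [int(v) for v in Label])
        if not valid.all():
            raise ValueError("label data contains values outside the label alphabet")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabelVolume):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and self.pixel_spacing_mm == other.pixel_spacing_mm
            and self.slice_spacing_mm == other.slice_spacing_mm
        )

    def label_counts(self) -> dict:
        """Total voxel count per label (sums to grid size by construction)."""
        counts = {name: 0 for name in LABEL_NAMES.values()}
        values, n = np.unique(self.data, return_counts=True)
        for v, c in zip(values, n):
            counts[LABEL_NAMES[int(v)]] = int(c)
        return counts

    def copy(self) -> "LabelVolume":
        return LabelVolume(
            self.data.copy(),
            self.pixel_spacing_mm,
            self.slice_spacing_mm,
            dict(self.meta),
        )


@dataclass
class SliceStack:
    """Ordered grayscale images in [0, 1] with physical spacing."""

    data: np.ndarray
    pixel_spacing_mm: float
    slice_spacing_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D (n_slices, ny, nx)")
        if self.pixel_spacing_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("spacings must be positive")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
            raise ValueError("stack intensities must lie in [0, 1]")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]
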