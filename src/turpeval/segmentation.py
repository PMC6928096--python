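"""Automated per-slice partition of B-mode images into the four regions.

Strategy: deterministic percentile contrast stretch, three-level intensity
classification (dark / mid / bright), morphological cleanup, then topology:
dark pixels 4-connected to the image border are background, the enclosed
dark component at (or nearest to) the cavity seed becomes the cavity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from turpeval.volume import Label, LabelVolume, SliceStack

__all__ = ["SegmentationParams", "SliceFlags", "SegmentationResult",
           "segment_slice", "segment_stack"]

_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the threshold-plus-topology segmenter.

    ``thresholds``: ``None`` selects automatic 3-class multi-Otsu cut
    points; a ``(low, high)`` pair fixes them (applied to the stretched
    image).  ``cleanup_radius_mm`` is the structuring-element radius for
    opening/closing; regions smaller than ``min_area_mm2`` are absorbed.
    ``seed_policy`` is ``"center"`` (slice center) or ``"propagate"``
    (centroid of the previous slice's cavity when available).
    """

    thresholds: tuple | None = None
    cleanup_radius_mm: float = 0.2
    min_area_mm2: float = 1.0
    seed_policy: str = "propagate"
    stretch_percentiles: tuple = (1.0, 99.0)
    min_class_contrast: float = 0.15

    def __post_init__(self) -> None:
        if self.thresholds is not None:
            lo, hi = self.thresholds
            if not lo < hi:
                raise ValueError("thresholds must be strictly ordered (low < high)")
        if self.cleanup_radius_mm < 0 or self.min_area_mm2 < 0:
            raise ValueError("cleanup radius and minimum area must be >= 0")
        if self.seed_policy not in ("center", "propagate"):
            raise ValueError("seed_policy must be 'center' or 'propagate'")


@dataclass(frozen=True)
class SliceFlags:
    """Per-slice quality flags; a slice with ``valid == False`` carries no
    metric values downstream."""

    cavity_found: bool
    central_found: bool
    unique_cavity: bool
    reason: str = ""

    @property
    def valid(self) -> bool:
        return self.cavity_found and self.unique_cavity


@dataclass
class SegmentationResult:
    """Inferred label stack, per-slice flags and provenance."""

    labels: LabelVolume
    flags: list
    provenance: dict = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return sum(f.valid for f in self.flags)


def _stretch(image: np.ndarray, percentiles: tuple) -> np.ndarray:
    lo, hi = np.percentile(image, percentiles)
    if hi - lo < 1e-6:
        return image.astype(np.float64)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def _classify(image: np.ndarray, params: SegmentationParams):
    """Three-level split plus an optional cavity cut-point.

    Returns ``(dark, mid, bright, cavity_cut)`` or ``None`` when the
    histogram is degenerate.  The automatic path is hierarchical Otsu: a
    global split into dark (cavity + background) and light (tissue), then a
    sub-split of the light side into peripheral/central — accepted only when
    the two sub-classes are separated by ``min_class_contrast``, so a slice
    without central tissue is not split spuriously.  The dark side's
    sub-threshold is kept to separate cavity from background when a breach
    connects them.  (A flat four-class multi-Otsu is unstable here: on
    gap-ridden slice histograms it can drop two thresholds into one gap,
    leaving an empty class.)
    """
    if params.thresholds is not None:
        lo, hi = params.thresholds
        cavity_cut = None
    else:
        if np.ptp(image) < 1e-6:
            return None
        lo = threshold_otsu(image)
        dark_px = image[image < lo]
        light_px = image[image >= lo]
        if dark_px.size == 0 or light_px.size == 0:
            return None
        hi = np.inf  # no central zone unless the light side clearly splits
        if np.ptp(light_px) > 1e-6:
            t_light = threshold_otsu(light_px)
            upper = light_px[light_px >= t_light]
            lower = light_px[light_px < t_light]
            if upper.size and lower.size and upper.mean() - lower.mean() >= params.min_class_contrast:
                hi = t_light
        cavity_cut = threshold_otsu(dark_px) if np.ptp(dark_px) > 1e-6 else None
    dark = image < lo
    bright = image >= hi
    mid = ~dark & ~bright
    return dark, mid, bright, cavity_cut


def segment_slice(image: np.ndarray, params: SegmentationParams,
                  pixel_spacing_mm: float, seed_point: tuple | None = None):
    """Segment one grayscale slice; returns ``(label_slice, flags)``.

    ``seed_point`` is the (row, col) cavity seed; defaults to the slice
    center.  A slice with no enclosed dark component is flagged rather than
    raising.  8-connectivity is used for regions, 4-connectivity for the
    background complement.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.min() < -1e-9 or image.max() > 1 + 1e-9:
        raise ValueError("slice intensities must lie in [0, 1]")
    ny, nx = image.shape
    if seed_point is None:
        seed_point = ((ny - 1) / 2.0, (nx - 1) / 2.0)

    labels = np.zeros(image.shape, dtype=np.uint8)
    stretched = _stretch(image, params.stretch_percentiles)
    classes = _classify(stretched, params)
    if classes is None:
        return labels, SliceFlags(False, False, False, reason="degenerate histogram")
    dark, mid, bright, cavity_cut = classes

    radius_px = int(round(params.cleanup_radius_mm / pixel_spacing_mm))
    if radius_px >= 1:
        selem = disk(radius_px).astype(bool)
        # erosion must treat off-image as foreground so border-touching dark
        # regions stay border-connected through the cleanup
        def _open_close(m):
            m = ndimage.binary_dilation(
                ndimage.binary_erosion(m, selem, border_value=1), selem, border_value=0)
            return ndimage.binary_erosion(
                ndimage.binary_dilation(m, selem, border_value=0), selem, border_value=1)
        bright = _open_close(bright)
        dark = _open_close(dark)
        dark &= ~bright
        mid = ~dark & ~bright

    min_area_px = params.min_area_mm2 / pixel_spacing_mm ** 2

    # dark pixels 4-connected to the border are background
    comp, n_comp = ndimage.label(dark, structure=_FOUR)
    border = np.zeros(image.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_ids = np.unique(comp[border & dark])
    background = np.isin(comp, border_ids[border_ids > 0])
    enclosed = dark & ~background

    # the embedding agar can land in the mid class; tissue never touches the
    # border, so mid components reaching it are background too
    mcomp, _ = ndimage.label(mid, structure=_FOUR)
    mborder = np.unique(mcomp[border & mid])
    mid_bg = np.isin(mcomp, mborder[mborder > 0])
    background |= mid_bg
    mid &= ~mid_bg

    # enclosed dark components large enough are cavity candidates
    ccomp, n_cc = ndimage.label(enclosed, structure=_EIGHT)
    candidates = []
    tissue = mid | bright
    for cid in range(1, n_cc + 1):
        mask = ccomp == cid
        area = int(mask.sum())
        touches_tissue = bool((ndimage.binary_dilation(mask, structure=_EIGHT) & tissue).any())
        if area >= min_area_px and touches_tissue:
            cy, cx = ndimage.center_of_mass(mask)
            candidates.append((cid, mask, (cy, cx)))
        else:
            mid |= mask  # absorb small enclosed dark specks into tissue
            enclosed &= ~mask

    if not candidates and cavity_cut is not None:
        # a peripheral breach can connect the cavity to the border dark
        # region; split that region at the darkest-class cut and retry
        sub = background & (stretched < cavity_cut)
        scomp, n_sc = ndimage.label(sub, structure=_EIGHT)
        for cid in range(1, n_sc + 1):
            mask = scomp == cid
            if mask.sum() < min_area_px:
                continue
            if not (ndimage.binary_dilation(mask, structure=_EIGHT) & tissue).any():
                continue
            cy, cx = ndimage.center_of_mass(mask)
            candidates.append((-cid, mask, (cy, cx)))
        for _, mask, _ in candidates:
            background &= ~mask

    cavity = np.zeros(image.shape, dtype=bool)
    if candidates:
        containing = [c for c in candidates
                      if c[1][int(round(seed_point[0])), int(round(seed_point[1]))]]
        if containing:
            chosen = containing[0]
        else:
            chosen = min(candidates, key=lambda c: (c[2][0] - seed_point[0]) ** 2
                         + (c[2][1] - seed_point[1]) ** 2)
        cavity = chosen[1]
        for cid, mask, _ in candidates:
            if cid != chosen[0]:
                if cid < 0:  # unchosen rescue fragments stay background
                    background |= mask
                else:
                    mid |= mask

    # small bright specks become tissue; remaining bright is central zone
    bcomp, n_bc = ndimage.label(bright, structure=_EIGHT)
    if n_bc:
        sizes = ndimage.sum_labels(np.ones_like(bcomp), bcomp, index=np.arange(1, n_bc + 1))
        small = np.isin(bcomp, np.nonzero(sizes < min_area_px)[0] + 1)
        mid |= small
        bright &= ~small

    labels[mid] = Label.PERIPHERAL
    labels[bright] = Label.CENTRAL
    labels[cavity] = Label.CAVITY
    # drop stray tissue islands lost in the background
    pcomp, n_pc = ndimage.label(labels != Label.BACKGROUND, structure=_EIGHT)
    if n_pc > 1:
        sizes = ndimage.sum_labels(np.ones_like(pcomp), pcomp, index=np.arange(1, n_pc + 1))
        keep = int(np.argmax(sizes)) + 1
        labels[(pcomp > 0) & (pcomp != keep)] = Label.BACKGROUND

    cavity_found = bool(cavity.any() and labels[cavity].any())
    flags = SliceFlags(
        cavity_found=cavity_found,
        central_found=bool(bright.any()),
        unique_cavity=len(candidates) <= 1 or bool(
            [c for c in candidates if c[1][int(round(seed_point[0])), int(round(seed_point[1]))]]
        ),
        reason="" if cavity_found else "no enclosed dark component",
    )
    if not cavity_found:
        labels = np.zeros(image.shape, dtype=np.uint8)
    return labels, flags


def segment_stack(stack: SliceStack, params: SegmentationParams) -> SegmentationResult:
    """Segment every slice, propagating the cavity seed along the stack."""
    if stack.n_slices == 0:
        raise ValueError("cannot segment an empty stack")
    out = np.zeros(stack.data.shape, dtype=np.uint8)
    flags = []
    seed_point = None
    for k in range(stack.n_slices):
        point = seed_point if params.seed_policy == "propagate" else None
        lab, fl = segment_slice(stack[k], params, stack.pixel_spacing_mm, seed_point=point)
        out[k] = lab
        flags.append(fl)
        if params.seed_policy == "propagate" and fl.valid:
            seed_point = ndimage.center_of_mass(lab == Label.CAVITY)
    checksum = hashlib.sha256(np.ascontiguousarray(stack.data).tobytes()).hexdigest()[:16]
    provenance = {
        "params": {
            "thresholds": list(params.thresholds) if params.thresholds else "otsu-hierarchical",
            "cleanup_radius_mm": params.cleanup_radius_mm,
            "min_area_mm2": params.min_area_mm2,
            "seed_policy": params.seed_policy,
        },
        "input_checksum": checksum,
    }
    labels = LabelVolume(out, stack.pixel_spacing_mm, stack.slice_spacing_mm,
                         meta={"kind": "segmented"})
    return SegmentationResult(labels=labels, flags=flags, provenance=provenance)
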