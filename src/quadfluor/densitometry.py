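"""Per-neuron densitometry: background, bleed-through, segmentation, measurement.

The measurement contract follows routine single-cell immunofluorescence
densitometry: the background signal of every channel is estimated once per
individual from a non-stained area and the derived thresholds are held
constant across that individual's sections; somata are delineated from the TH
channel; mean intensities of all four channels are read out simultaneously
over each soma, background-corrected by subtracting the background mean, and
capped at 100 cells per section.  Cells are never excluded for low CI-20,
CIV-1 or porin signal — deficiency is exactly what is being measured.

Bleed-through between filter sets is estimated from single-label controls as
a linear crosstalk matrix; computational unmixing is provided as an optional
correction (off by default — well-chosen fluorophores and acquisition-side
threshold adjustment make residual crosstalk negligible in the emulated
protocol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .channels import MARKERS, SectionImage, marker_index
from .errors import ValidationError
from .imgio import CellROI, empty_measurements

RegionLike = Union[np.ndarray, Tuple[int, int, int, int]]


@dataclass
class BackgroundModel:
    """Per-channel background statistics of one individual.

    ``threshold = mean + k * sd`` per channel; one model is estimated per
    individual and applied unchanged to all of that individual's sections.
    """

    individual_id: str
    mean: np.ndarray  # len-4, canonical marker order
    sd: np.ndarray
    k: float = 2.0
    n_pixels: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (4,) or self.sd.shape != (4,):
            raise ValidationError("background mean and sd must be length-4 vectors")
        if np.any(self.sd < 0) or self.k < 0:
            raise ValidationError("background sd and k must be non-negative")

    @property
    def threshold(self) -> np.ndarray:
        return self.mean + self.k * self.sd

    def for_marker(self, marker: str) -> Tuple[float, float, float]:
        i = marker_index(marker)
        return float(self.mean[i]), float(self.sd[i]), float(self.threshold[i])


@dataclass
class CrosstalkMatrix:
    """Linear bleed-through: ``matrix[i, j]`` is the fraction of channel j's
    true signal appearing in acquired channel i (canonical marker order)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float)
        if A.shape != (4, 4):
            raise ValidationError("crosstalk matrix must be 4 x 4")
        if not np.allclose(np.diag(A), 1.0):
            raise ValidationError("crosstalk diagonal must be 1")
        off = A[~np.eye(4, dtype=bool)]
        if np.any(off < 0) or np.any(off >= 1):
            raise ValidationError("off-diagonal crosstalk must lie in [0, 1)")
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValidationError("crosstalk matrix is singular")
        self.matrix = A

    @classmethod
    def identity(cls) -> "CrosstalkMatrix":
        return cls(np.eye(4))


def _region_mask(region: RegionLike, shape: Tuple[int, int]) -> np.ndarray:
    if isinstance(region, tuple):
        r0, c0, r1, c1 = region
        if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
            raise ValidationError(f"background rectangle {region} outside image {shape}")
        mask = np.zeros(shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
        return mask
    mask = np.asarray(region)
    if mask.dtype != bool or mask.shape != shape:
        raise ValidationError("background region must be a boolean mask of image shape or a rectangle")
    return mask


def estimate_background(
    image: SectionImage,
    region: RegionLike,
    k: float = 2.0,
    *,
    rois: Optional[Sequence[CellROI]] = None,
    min_pixels: int = 100,
) -> BackgroundModel:
    """Estimate per-channel background from a non-stained area.

    ``region`` is a boolean mask or a half-open rectangle ``(r0, c0, r1, c1)``.
    It must be disjoint from any supplied ROI.  Mean and sample SD (ddof=1)
    are computed per channel; the detection threshold is ``mean + k * sd``.
    """
    mask = _region_mask(region, image.shape)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("background region is empty")
    if n < min_pixels:
        raise ValidationError(f"background region has {n} px; at least {min_pixels} required")
    if rois:
        for roi in rois:
            if mask[roi.rows, roi.cols].any():
                raise ValidationError(
                    f"background region overlaps ROI of cell {roi.cell_id}"
                )
    values = image.pixels[mask].astype(float)  # n x 4
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if n > 1 else np.zeros(4)
    return BackgroundModel(
        individual_id=image.subject_id, mean=mean, sd=sd, k=float(k), n_pixels=n
    )


def estimate_crosstalk(
    single_label_images: Mapping[str, SectionImage],
    backgrounds: Mapping[str, BackgroundModel],
) -> CrosstalkMatrix:
    """Estimate the bleed-through matrix from single-label control sections.

    For the control labelled only with marker ``j``, pixels above the
    control's own-channel threshold define the labelled objects;
    ``alpha[i, j]`` is the ratio of background-corrected channel-i to
    channel-j means over those pixels.  Diagonal entries are forced to 1;
    negative estimates (noise) are clamped to 0 with a warning.
    """
    missing = [m for m in MARKERS if m not in single_label_images]
    if missing:
        raise ValidationError(f"missing single-label control(s) for: {missing}")
    A = np.eye(4)
    for j, marker in enumerate(MARKERS):
        img = single_label_images[marker]
        bg = backgrounds[marker]
        _, _, t = bg.for_marker(marker)
        own = img.channel(marker).astype(float)
        objects = own > t
        if not objects.any():
            raise ValidationError(
                f"single-label control for {marker}: no pixels above its own-channel threshold"
            )
        corrected = img.pixels[objects].astype(float).mean(axis=0) - bg.mean
        if corrected[j] <= 0:
            raise ValidationError(
                f"single-label control for {marker}: own-channel corrected signal is not positive"
            )
        col = corrected / corrected[j]
        neg = col < 0
        if neg.any():
            warnings.warn(
                f"negative crosstalk estimate(s) for {marker} clamped to 0", stacklevel=2
            )
            col[neg] = 0.0
        A[:, j] = col
        A[j, j] = 1.0
    return CrosstalkMatrix(A)


def correct_crosstalk(
    image: SectionImage, matrix: CrosstalkMatrix, background: BackgroundModel
) -> SectionImage:
    """Per-pixel linear unmixing: ``true = A^-1 (obs - mu_b) + mu_b``.

    The observed background level is left in place so downstream background
    subtraction behaves identically on mixed and unmixed images.  With an
    identity matrix the image is returned unchanged.
    """
    A = matrix.matrix
    if np.allclose(A, np.eye(4)):
        return image
    A_inv = np.linalg.inv(A)
    px = image.pixels.astype(float)
    mu = background.mean
    unmixed = (px - mu) @ A_inv.T + mu
    unmixed = np.rint(np.clip(unmixed, 0, image.ceiling)).astype(image.pixels.dtype)
    return SectionImage(
        pixels=unmixed,
        subject_id=image.subject_id,
        group_label=image.group_label,
        run_id=image.run_id,
        section_id=image.section_id,
        bit_depth=image.bit_depth,
        channels=image.channels,
    )


def segment_cells(
    image: SectionImage,
    background: BackgroundModel,
    *,
    min_area: int = 100,
    exclude_border: bool = True,
) -> List[CellROI]:
    """Delineate somata from the TH channel.

    The TH plane is binarized at the individual's TH threshold, holes are
    filled, and 8-connected components are kept if they reach ``min_area``
    pixels and (by default) do not touch the image border — partial somata at
    the field edge would bias mean intensities.  ROIs are returned sorted by
    centroid (row, col) so downstream capping is deterministic.  An empty
    result is valid.
    """
    _, _, t = background.for_marker("TH")
    binary = image.channel("TH").astype(float) > t
    binary = ndimage.binary_fill_holes(binary)
    labels = cc_label(binary, connectivity=2)
    H, W = image.shape
    rois: List[Tuple[Tuple[float, float], np.ndarray, np.ndarray]] = []
    for prop in regionprops(labels):
        if prop.area < min_area:
            continue
        r0, c0, r1, c1 = prop.bbox
        if exclude_border and (r0 == 0 or c0 == 0 or r1 == H or c1 == W):
            continue
        rr, cc = np.nonzero(labels == prop.label)
        rois.append((prop.centroid, rr, cc))
    rois.sort(key=lambda item: item[0])
    return [
        CellROI(i + 1, rr, cc, section_id=image.section_id, source="automatic")
        for i, (_, rr, cc) in enumerate(rois)
    ]


def measure_cells(
    image: SectionImage,
    rois: Sequence[CellROI],
    background: BackgroundModel,
    cap: int = 100,
) -> pd.DataFrame:
    """Simultaneous per-channel mean intensities for each soma.

    ROIs are processed in centroid (row, col) order and truncated at ``cap``
    per section.  For every ROI the raw mean of each channel is taken over
    *all* ROI pixels (no per-pixel thresholding — low-abundance cells carry
    exactly the signal they have) and corrected as ``max(0, raw - mu_b)``.
    Returns a measurement table; ratio columns are left unset.
    """
    if cap < 1:
        raise ValidationError("cap must be >= 1")
    ordered = sorted(rois, key=lambda r: r.centroid)[: int(cap)]
    rows = []
    for roi in ordered:
        if not roi.within(image.shape):
            raise ValidationError(f"ROI {roi.cell_id} out of bounds for image {image.shape}")
        raw = image.pixels[roi.rows, roi.cols, :].astype(float).mean(axis=0)
        corr = np.clip(raw - background.mean, 0.0, None)
        rec = {
            "subject": image.subject_id,
            "group": image.group_label,
            "run": image.run_id,
            "section": image.section_id,
            "cell_id": roi.cell_id,
            "area": roi.area,
        }
        for i, m in enumerate(MARKERS):
            rec[f"raw_{m.lower()}"] = raw[i]
            rec[f"corr_{m.lower()}"] = corr[i]
        rows.append(rec)
    if not rows:
        return empty_measurements()
    df = pd.DataFrame(rows)
    for name in ("ci_porin", "civ_porin", "ci_civ"):
        df[f"ratio_{name}"] = np.nan
        df[f"norm_{name}"] = np.nan
    df["excluded"] = False
    df["exclude_reason"] = ""
    return df[list(empty_measurements().columns)]
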