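"""On-disk artifacts: multi-channel TIFFs, ROI masks/polygons, tables, manifests.

Conventions
-----------
* Multi-channel section TIFFs store planes in canonical marker order
  ``(TH, CI20, CIV1, porin)`` with a JSON description tag recording markers,
  emission wavelengths, identity fields and bit depth.  Per-channel files are
  matched by wavelength suffix (``_405``/``_488``/``_546``/``_647``).
  Channel-to-marker mapping must be total and unambiguous; the reader raises
  rather than assuming an order.
* ROIs exchange as label-mask TIFF (canonical, lossless) or polygon JSON.
  Polygons are rasterized with an even-odd fill over pixel centers, 0-based,
  half-open: pixel (r, c) belongs to the ROI iff its center (r+0.5, c+0.5)
  falls inside the outline.
* Measurement tables are CSV with a fixed column schema; floats round-trip at
  repr precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from .channels import (
    EMISSION_NM,
    MARKERS,
    N_CHANNELS,
    SectionImage,
    WAVELENGTH_TO_MARKER,
)
from .errors import ChannelMappingError, RoiOverlapError, SchemaError, ValidationError

# ---------------------------------------------------------------------------
# section images
# ---------------------------------------------------------------------------


def write_section_image(image: SectionImage, path) -> None:
    """Write a multi-channel TIFF (planes in canonical marker order)."""
    path = Path(path)
    meta = {
        "markers": list(MARKERS),
        "emission_nm": [EMISSION_NM[m] for m in MARKERS],
        "subject_id": image.subject_id,
        "group_label": image.group_label,
        "run_id": int(image.run_id),
        "section_id": int(image.section_id),
        "bit_depth": int(image.bit_depth),
    }
    planes = np.ascontiguousarray(image.pixels.transpose(2, 0, 1))
    tifffile.imwrite(path, planes, photometric="minisblack", description=json.dumps(meta))


def _identity_fields(meta: Mapping, manifest_row: Optional[Mapping]) -> Dict:
    row = {} if manifest_row is None else dict(manifest_row)
    return {
        "subject_id": str(row.get("subject", meta.get("subject_id", "unknown"))),
        "group_label": str(row.get("group", meta.get("group_label", "unknown"))),
        "run_id": int(row.get("run", meta.get("run_id", 0))),
        "section_id": int(row.get("section", meta.get("section_id", 0))),
    }


def read_section_image(
    path_or_paths: Union[str, Path, Sequence[Union[str, Path]]],
    manifest_row: Optional[Mapping] = None,
) -> SectionImage:
    """Read one section: a single multi-channel TIFF, or four per-channel
    TIFFs with ``_405/_488/_546/_647`` wavelength suffixes.

    Channel-to-marker mapping comes from the TIFF metadata (multi-channel) or
    the filename suffix (per-channel); an unmappable or incomplete channel set
    raises :class:`ChannelMappingError`.
    """
    if isinstance(path_or_paths, (str, Path)):
        return _read_multichannel(Path(path_or_paths), manifest_row)
    paths = [Path(p) for p in path_or_paths]
    if len(paths) != N_CHANNELS:
        raise ChannelMappingError(f"expected {N_CHANNELS} per-channel files, got {len(paths)}")
    by_marker: Dict[str, np.ndarray] = {}
    for p in paths:
        stem = p.stem
        suffix = stem.rsplit("_", 1)[-1]
        try:
            marker = WAVELENGTH_TO_MARKER[int(suffix)]
        except (ValueError, KeyError):
            raise ChannelMappingError(
                f"cannot map {p.name!r} to a channel: expected a wavelength "
                f"suffix in {sorted(WAVELENGTH_TO_MARKER)}"
            ) from None
        if marker in by_marker:
            raise ChannelMappingError(f"duplicate channel file for {marker} ({p.name})")
        plane = tifffile.imread(p)
        if plane.ndim != 2:
            raise ChannelMappingError(f"{p.name} is not a single-channel image")
        by_marker[marker] = plane
    missing = [m for m in MARKERS if m not in by_marker]
    if missing:
        raise ChannelMappingError(f"missing channel(s): {missing}")
    pixels = np.stack([by_marker[m] for m in MARKERS], axis=-1)
    bit_depth = 8 if pixels.dtype == np.uint8 else 16
    fields = _identity_fields({}, manifest_row)
    return SectionImage(pixels=pixels, bit_depth=bit_depth, **fields)


def _read_multichannel(path: Path, manifest_row: Optional[Mapping]) -> SectionImage:
    with tifffile.TiffFile(path) as tif:
        planes = tif.asarray()
        desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
        markers = list(meta["markers"])
    except (json.JSONDecodeError, KeyError, TypeError):
        raise ChannelMappingError(
            f"{path.name} lacks channel metadata; cannot map planes to markers"
        ) from None
    if planes.ndim != 3 or planes.shape[0] != N_CHANNELS:
        raise ChannelMappingError(
            f"{path.name}: expected {N_CHANNELS} planes, got shape {planes.shape}"
        )
    if sorted(markers) != sorted(MARKERS):
        raise ChannelMappingError(f"{path.name}: unrecognized marker set {markers}")
    order = [markers.index(m) for m in MARKERS]
    pixels = np.stack([planes[i] for i in order], axis=-1)
    bit_depth = int(meta.get("bit_depth", 8 if pixels.dtype == np.uint8 else 16))
    fields = _identity_fields(meta, manifest_row)
    return SectionImage(pixels=pixels, bit_depth=bit_depth, **fields)


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------


@dataclass
class CellROI:
    """A delineated soma: the set of pixels belonging to one cell."""

    cell_id: int
    rows: np.ndarray
    cols: np.ndarray
    section_id: int = 0
    source: str = "automatic"  # or "manual"

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        if self.rows.shape != self.cols.shape or self.rows.ndim != 1:
            raise ValidationError("rows and cols must be matching 1-D arrays")
        if self.rows.size == 0:
            raise ValidationError("ROI must contain at least one pixel")
        if self.source not in ("manual", "automatic"):
            raise ValidationError("source must be 'manual' or 'automatic'")

    @property
    def area(self) -> int:
        return int(self.rows.size)

    @property
    def centroid(self) -> Tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    def within(self, shape: Tuple[int, int]) -> bool:
        return bool(
            (self.rows >= 0).all()
            and (self.cols >= 0).all()
            and (self.rows < shape[0]).all()
            and (self.cols < shape[1]).all()
        )


def write_label_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=np.uint16), photometric="minisblack")


def read_label_mask(path) -> np.ndarray:
    mask = tifffile.imread(Path(path))
    if mask.ndim != 2:
        raise ValidationError(f"{Path(path).name} is not a 2-D label mask")
    return mask.astype(np.uint16)


def rois_to_label_mask(rois: Sequence[CellROI], shape: Tuple[int, int]) -> np.ndarray:
    """Render ROIs into a label mask; overlapping ROIs raise."""
    mask = np.zeros(shape, dtype=np.uint16)
    for roi in rois:
        if not roi.within(shape):
            raise ValidationError(f"ROI {roi.cell_id} extends outside the image")
        taken = mask[roi.rows, roi.cols]
        clash = taken[taken != 0]
        if clash.size:
            raise RoiOverlapError(
                f"cell {roi.cell_id} overlaps cell(s) {sorted(set(int(x) for x in clash))}"
            )
        mask[roi.rows, roi.cols] = roi.cell_id
    return mask


def label_mask_to_rois(mask: np.ndarray, *, source: str = "manual", section_id: int = 0) -> List[CellROI]:
    rois = []
    for label in np.unique(mask):
        if label == 0:
            continue
        rr, cc = np.nonzero(mask == label)
        rois.append(CellROI(int(label), rr, cc, section_id=section_id, source=source))
    return rois


def rasterize_polygon(polygon: Sequence[Sequence[float]], shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    """Even-odd rasterization of a closed (row, col) polygon.

    A pixel belongs to the polygon iff its center lies inside by the even-odd
    (crossing-number) rule; half-open by construction, so a square with
    corners (0,0)-(10,10) covers exactly 100 pixels.  Hand-rolled because the
    convention itself is the contract (library rasterizers pin different
    boundary rules).
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValidationError("polygon must be an N x 2 array of (row, col) vertices, N >= 3")
    r0 = max(int(np.floor(poly[:, 0].min())), 0)
    r1 = min(int(np.ceil(poly[:, 0].max())) + 1, shape[0])
    c0 = max(int(np.floor(poly[:, 1].min())), 0)
    c1 = min(int(np.ceil(poly[:, 1].max())) + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        raise ValidationError("polygon lies outside the image")
    rr, cc = np.mgrid[r0:r1, c0:c1]
    pr = rr + 0.5
    pc = cc + 0.5
    inside = np.zeros(pr.shape, dtype=bool)
    v = np.vstack([poly, poly[:1]])
    for (ar, ac), (br, bc) in zip(v[:-1], v[1:]):
        crosses = (ar > pr) != (br > pr)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = ac + (pr - ar) * (bc - ac) / (br - ar)
        inside ^= crosses & (pc < x_at)
    return rr[inside], cc[inside]


def write_rois(rois: Sequence[CellROI], path, *, image_shape: Optional[Tuple[int, int]] = None) -> None:
    """Write ROIs as a label-mask TIFF (the canonical exchange format)."""
    if image_shape is None:
        image_shape = (
            int(max(r.rows.max() for r in rois)) + 1,
            int(max(r.cols.max() for r in rois)) + 1,
        )
    write_label_mask(rois_to_label_mask(rois, image_shape), path)


def read_rois(path, *, section_id: int = 0) -> List[CellROI]:
    """Read ROIs from a label-mask TIFF or a polygon JSON file.

    Polygon JSON: ``{"image_shape": [H, W], "rois": [{"cell_id": k,
    "polygon": [[r, c], ...]}, ...]}``.  Overlapping polygons raise
    :class:`RoiOverlapError` naming the offending cell ids.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return label_mask_to_rois(read_label_mask(path), section_id=section_id)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        shape = tuple(payload["image_shape"])
        rois = []
        for entry in payload["rois"]:
            rr, cc = rasterize_polygon(entry["polygon"], shape)
            if rr.size == 0:
                raise ValidationError(f"polygon for cell {entry['cell_id']} rasterizes to 0 pixels")
            rois.append(
                CellROI(int(entry["cell_id"]), rr, cc, section_id=section_id, source="manual")
            )
        rois_to_label_mask(rois, shape)  # overlap check
        return rois
    raise ValidationError(f"unsupported ROI format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# measurement tables and manifests
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS: Tuple[str, ...] = (
    "subject",
    "group",
    "run",
    "section",
    "cell_id",
    "area",
    "raw_th",
    "raw_ci20",
    "raw_civ1",
    "raw_porin",
    "corr_th",
    "corr_ci20",
    "corr_civ1",
    "corr_porin",
    "ratio_ci_porin",
    "ratio_civ_porin",
    "ratio_ci_civ",
    "norm_ci_porin",
    "norm_civ_porin",
    "norm_ci_civ",
    "excluded",
    "exclude_reason",
)


def empty_measurements() -> pd.DataFrame:
    return pd.DataFrame(columns=list(MEASUREMENT_COLUMNS))


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement table is missing column(s): {missing}")
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    validate_measurements(df)
    # shortest-repr float formatting so read(write(x)) == x bitwise
    df.loc[:, list(MEASUREMENT_COLUMNS)].to_csv(
        Path(path), index=False, float_format=lambda x: repr(float(x))
    )


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    validate_measurements(df)
    df["excluded"] = df["excluded"].astype(bool)
    df["exclude_reason"] = df["exclude_reason"].fillna("")
    return df


def read_manifest(dataset_dir) -> pd.DataFrame:
    dataset_dir = Path(dataset_dir)
    manifest = pd.read_csv(dataset_dir / "manifest.csv")
    required = {"subject", "group", "run", "section", "image", "bg_r0", "bg_c0", "bg_r1", "bg_c1"}
    missing = sorted(required - set(manifest.columns))
    if missing:
        raise SchemaError(f"manifest is missing column(s): {missing}")
    return manifest
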