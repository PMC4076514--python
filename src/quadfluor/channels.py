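"""Channel conventions for the quadruple-label panel.

The panel labels four targets in one midbrain section: tyrosine hydroxylase
(TH, dopaminergic-neuron marker, 405 nm emission), complex I subunit NDUFB8
("CI-20", 488 nm), complex IV subunit COX1 ("CIV-1", 546 nm) and the
outer-membrane channel porin/VDAC1 (mitochondrial-mass marker, 647 nm).

In-memory pixel arrays always use the canonical marker order
``(TH, CI20, CIV1, porin)``.  Acquisition order is the reverse: channels are
imaged longest emission wavelength first to limit bleed-through, so
acquisition index 0 is the 647 nm porin channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

MARKERS: Tuple[str, ...] = ("TH", "CI20", "CIV1", "porin")

EMISSION_NM = {"TH": 405, "CI20": 488, "CIV1": 546, "porin": 647}

#: wavelength suffix used by per-channel file naming, e.g. ``section_405.tif``
WAVELENGTH_TO_MARKER = {nm: m for m, nm in EMISSION_NM.items()}

N_CHANNELS = len(MARKERS)


def marker_index(marker: str) -> int:
    """Index of ``marker`` in the canonical channel order."""
    try:
        return MARKERS.index(marker)
    except ValueError:
        raise KeyError(f"unknown marker {marker!r}; expected one of {MARKERS}") from None


@dataclass(frozen=True)
class ChannelSpec:
    """One fluorescence channel: what it labels and when it was acquired."""

    marker: str
    emission_wavelength_nm: int
    acquisition_index: int

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if self.emission_wavelength_nm != EMISSION_NM[self.marker]:
            raise ValueError(
                f"{self.marker} must be the {EMISSION_NM[self.marker]} nm channel, "
                f"got {self.emission_wavelength_nm} nm"
            )


def default_channels() -> Tuple[ChannelSpec, ...]:
    """Channel specs in canonical order, acquisition longest wavelength first."""
    by_wavelength = sorted(MARKERS, key=lambda m: EMISSION_NM[m], reverse=True)
    acq = {m: i for i, m in enumerate(by_wavelength)}
    return tuple(ChannelSpec(m, EMISSION_NM[m], acq[m]) for m in MARKERS)


@dataclass
class SectionImage:
    """One 4-channel image of one tissue section.

    ``pixels`` is an ``H x W x 4`` non-negative integer array in canonical
    marker order; intensities are arbitrary fluorescence units bounded by the
    camera bit depth.
    """

    pixels: np.ndarray
    subject_id: str
    group_label: str
    run_id: int
    section_id: int
    bit_depth: int = 16
    channels: Tuple[ChannelSpec, ...] = field(default_factory=default_channels)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != N_CHANNELS:
            raise ValueError(f"pixels must be H x W x {N_CHANNELS}, got shape {px.shape}")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("section images must be at least 64 x 64 pixels")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixel values must be integers (camera counts)")
        ceiling = 2**self.bit_depth - 1
        if px.min() < 0 or px.max() > ceiling:
            raise ValueError(f"pixel values must lie in [0, {ceiling}]")
        if tuple(c.marker for c in self.channels) != MARKERS:
            raise ValueError(f"channels must be in canonical order {MARKERS}")
        self.pixels = px

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def ceiling(self) -> int:
        return 2**self.bit_depth - 1

    def channel(self, marker: str) -> np.ndarray:
        """The 2-D plane for ``marker``."""
        return self.pixels[:, :, marker_index(marker)]
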