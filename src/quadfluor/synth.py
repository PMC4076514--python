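"""Synthetic midbrain-cohort generator.

Builds per-cell ground-truth fluorescence states and renders them into
4-channel section images with the statistical structure the densitometric
analysis assumes, so the full pipeline (background estimation, segmentation,
measurement, ratio normalization, cohort statistics) is testable without any
tissue data.

Model
-----
Each dopaminergic neuron is a disk whose expected intensity in the porin
channel is lognormal around a cohort baseline scaled by the subject's
mitochondrial-mass factor.  The complex-subunit channels are tied to porin:

    porin  = B_porin * porin_factor * exp(sigma * Z_p)
    CI-20  = porin * (B_CI / B_porin) * m_CI'  * exp(s_sh * Z_s + s_un * Z_ci)
    CIV-1  = porin * (B_CIV / B_porin) * m_CIV' * exp(s_sh * Z_s + s_un * Z_civ)

with ``sigma = sqrt(log(1 + cv^2))`` and the ratio-noise variance split into a
component ``Z_s`` shared by both complex channels (per-cell fixation and
epitope-accessibility effects act on both inner-membrane targets alike) and
channel-specific parts, ``s_sh^2 + s_un^2 = sigma^2``.  A Bernoulli draw per
channel replaces a cell's level with a near-zero "completely deficient" level
(5 % of the control median, so deficient cells are visibly dark but nonzero).
TH is drawn independently — it marks the neuron, not its mitochondria.

Because the deficient fraction f removes probability mass from the bottom of
the ratio distribution, the non-deficient branch multiplier ``m'`` is solved in
closed form so the *population median* of CI:porin equals the profile's
configured multiplier times the control baseline:

    m' = m_target / exp(sigma * Phi^-1(p)),
    p  = (1/2 - f * F_d(m_target)) / (1 - f)            (f < 1/2)

where ``F_d`` is the CDF of the deficient branch's ratio distribution (see
:func:`effective_multiplier`).

Rendering adds a Gaussian background field, sparse broadband autofluorescence
grains (residual lipofuscin after Sudan-black quenching), optional linear
inter-channel bleed-through, and Poisson–Gaussian camera noise, then clips to
bit depth.  A single gain applies across a whole cohort, emulating constant
exposure times across sections.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .channels import MARKERS, SectionImage
from .errors import PlacementError, ValidationError

GROUPS = ("control", "sng_del", "merrf", "pd")

#: control-cohort median expected intensities (camera counts, 16-bit scale)
BASELINE_MEDIANS: Dict[str, float] = {
    "TH": 12000.0,
    "CI20": 6000.0,
    "CIV1": 6000.0,
    "porin": 8000.0,
}

#: "completely deficient" cells sit at this fraction of the control median —
#: visibly dark yet nonzero, keeping background estimation well-posed
DEFICIENT_LEVEL_FRACTION = 0.05

#: fraction of the ratio-noise log-variance shared between CI-20 and CIV-1
SHARED_DISPERSION_FRACTION = 0.65

#: dispersion of the (mitochondria-independent) TH channel
TH_CV = 0.25


@dataclass(frozen=True)
class PatientProfile:
    """Generator truth for one subject's cohort of dopaminergic neurons.

    Ratio multipliers are medians relative to the control cohort (control =
    1.0); ``frac_*_deficient`` are the fractions of cells with near-zero
    complex-subunit signal; ``porin_factor`` scales mitochondrial mass.
    """

    group_label: str
    ci_porin_mult: float = 1.0
    civ_porin_mult: float = 1.0
    porin_factor: float = 1.0
    frac_ci_deficient: float = 0.0
    frac_civ_deficient: float = 0.0
    dispersion_cv: float = 0.35
    cells_per_section: int = 100
    sections_per_run: int = 1
    runs: int = 4

    def __post_init__(self) -> None:
        if self.group_label not in GROUPS:
            raise ValidationError(f"group_label must be one of {GROUPS}")
        for name in ("ci_porin_mult", "civ_porin_mult", "porin_factor"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("frac_ci_deficient", "frac_civ_deficient"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.dispersion_cv < 0:
            raise ValidationError("dispersion_cv must be >= 0")
        if self.cells_per_section < 1:
            raise ValidationError("cells_per_section must be >= 1")
        if self.runs < 1 or self.sections_per_run < 1:
            raise ValidationError("runs and sections_per_run must be >= 1")


def make_default_profiles() -> Tuple[PatientProfile, ...]:
    """The four default subjects: control, single large-scale mtDNA deletion,
    m.8344A>G MERRF, and idiopathic Parkinson's disease.

    True median multipliers encode the pooled combined-run medians reported
    for this four-subject design (CI-20:porin 100/19/33/32 %, CIV-1:porin
    100/60/32/42 %); deficient-cell fractions come from the prior
    population-level chromogen study of the same mitochondrial-disease cases
    (deletion: 44 % CI / 1 % CIV; MERRF: 22 % CI / 23 % CIV).  Porin is
    elevated in MERRF neurons (increased mitochondrial biogenesis; the
    magnitude is a documented generator default, not a measured value) and
    only slightly in PD.
    """
    return (
        PatientProfile("control"),
        PatientProfile(
            "sng_del",
            ci_porin_mult=0.19,
            civ_porin_mult=0.60,
            frac_ci_deficient=0.44,
            frac_civ_deficient=0.01,
        ),
        PatientProfile(
            "merrf",
            ci_porin_mult=0.33,
            civ_porin_mult=0.32,
            porin_factor=1.5,
            frac_ci_deficient=0.22,
            frac_civ_deficient=0.23,
        ),
        PatientProfile(
            "pd",
            ci_porin_mult=0.32,
            civ_porin_mult=0.42,
            porin_factor=1.1,
        ),
    )


@dataclass
class TrueCellState:
    """Latent ground truth for one rendered neuron."""

    cell_id: int
    radius: float
    expected: Dict[str, float]
    deficient_ci: bool
    deficient_civ: bool
    center: Optional[Tuple[float, float]] = None  # (row, col), set at render time

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("radius must be positive")
        for m in MARKERS:
            v = self.expected.get(m)
            if v is None or not np.isfinite(v) or v < 0:
                raise ValidationError(f"expected intensity for {m} must be finite and >= 0")


def effective_multiplier(
    target_mult: float,
    frac_deficient: float,
    sigma: float,
    *,
    deficient_median_mult: float = 0.0,
) -> float:
    """Non-deficient-branch median multiplier that pins the population median.

    The population ratio distribution is a two-component lognormal mixture:
    a fraction ``f`` of deficient cells (ratio lognormal with median
    ``deficient_median_mult`` in multiplier units and log-SD ``sigma * sqrt2``,
    since numerator and denominator fluctuate independently there) and the
    non-deficient branch (median ``m'``, log-SD ``sigma``).  The mixture
    median equals the target when the non-deficient branch puts its
    ``p = (1/2 - f * F_d(target)) / (1 - f)`` quantile at the target, so

        m' = target / exp(sigma * Phi^-1(p)).

    ``F_d(target)`` is the deficient branch's CDF at the target; for a target
    well above the deficient level it is ~1 and the formula reduces to the
    naive ``p = (1/2 - f)/(1 - f)``.  Requires the median to fall in the
    non-deficient mass (``f < 1/2``).
    """
    if frac_deficient >= 0.5:
        raise ValidationError(
            "frac_deficient >= 0.5: the population median falls inside the "
            "deficient mass and the ratio multiplier cannot be calibrated"
        )
    f = frac_deficient
    if f > 0 and deficient_median_mult > 0:
        if sigma > 0:
            z = np.log(target_mult / deficient_median_mult) / (sigma * np.sqrt(2.0))
            f_d = float(norm.cdf(z))
        else:
            f_d = 1.0 if target_mult > deficient_median_mult else 0.0
    else:
        f_d = 1.0
    p = (0.5 - f * f_d) / (1.0 - f)
    if not 0.0 < p < 1.0:
        raise ValidationError(
            "deficient branch overlaps the target median too strongly; "
            "cannot calibrate the ratio multiplier"
        )
    return target_mult / float(np.exp(sigma * norm.ppf(p)))


def generate_cell_population(
    profile: PatientProfile,
    n_cells: int,
    seed: int,
    *,
    baseline: Optional[Dict[str, float]] = None,
    shared_dispersion_fraction: float = SHARED_DISPERSION_FRACTION,
    radius_range: Tuple[float, float] = (8.0, 15.0),
) -> List[TrueCellState]:
    """Draw the latent per-cell intensity states for one section.

    Expected intensities are rounded to whole camera counts so that a
    noiseless rendering reproduces them exactly.  The same ``(profile,
    n_cells, seed)`` always yields an identical population.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if not 0.0 <= shared_dispersion_fraction <= 1.0:
        raise ValidationError("shared_dispersion_fraction must lie in [0, 1]")
    base = dict(BASELINE_MEDIANS if baseline is None else baseline)

    cv = profile.dispersion_cv
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    s_sh = sigma * float(np.sqrt(shared_dispersion_fraction))
    s_un = sigma * float(np.sqrt(1.0 - shared_dispersion_fraction))
    sigma_th = float(np.sqrt(np.log1p(TH_CV * TH_CV)))

    # deficient cells sit at a fixed fraction of the *control* median level,
    # so their ratio median in multiplier units scales with 1/porin_factor
    def_mult = DEFICIENT_LEVEL_FRACTION / profile.porin_factor
    m_ci = effective_multiplier(
        profile.ci_porin_mult, profile.frac_ci_deficient, sigma,
        deficient_median_mult=def_mult,
    )
    m_civ = effective_multiplier(
        profile.civ_porin_mult, profile.frac_civ_deficient, sigma,
        deficient_median_mult=def_mult,
    )

    rng = np.random.default_rng(seed)
    z_porin = rng.standard_normal(n_cells)
    z_shared = rng.standard_normal(n_cells)
    z_ci = rng.standard_normal(n_cells)
    z_civ = rng.standard_normal(n_cells)
    u_ci = rng.random(n_cells)
    u_civ = rng.random(n_cells)
    z_def_ci = rng.standard_normal(n_cells)
    z_def_civ = rng.standard_normal(n_cells)
    z_th = rng.standard_normal(n_cells)
    radii = rng.uniform(*radius_range, size=n_cells)

    porin = base["porin"] * profile.porin_factor * np.exp(sigma * z_porin)
    ci = porin * (base["CI20"] / base["porin"]) * m_ci * np.exp(s_sh * z_shared + s_un * z_ci)
    civ = porin * (base["CIV1"] / base["porin"]) * m_civ * np.exp(s_sh * z_shared + s_un * z_civ)

    def_ci = u_ci < profile.frac_ci_deficient
    def_civ = u_civ < profile.frac_civ_deficient
    ci = np.where(def_ci, DEFICIENT_LEVEL_FRACTION * base["CI20"] * np.exp(sigma * z_def_ci), ci)
    civ = np.where(
        def_civ, DEFICIENT_LEVEL_FRACTION * base["CIV1"] * np.exp(sigma * z_def_civ), civ
    )
    th = base["TH"] * np.exp(sigma_th * z_th)

    expected = np.column_stack([th, ci, civ, porin])  # canonical marker order
    expected = np.rint(expected)

    return [
        TrueCellState(
            cell_id=i + 1,
            radius=float(radii[i]),
            expected={m: float(expected[i, j]) for j, m in enumerate(MARKERS)},
            deficient_ci=bool(def_ci[i]),
            deficient_civ=bool(def_civ[i]),
        )
        for i in range(n_cells)
    ]


@dataclass(frozen=True)
class RenderParams:
    """Geometry, background and noise knobs for section rendering.

    Defaults emulate routine epifluorescence acquisition of a 1024 x 1024
    16-bit field: flat background with mild pixel noise, sparse broadband
    autofluorescence grains, shot plus read noise, no bleed-through (the
    acquisition protocol being emulated minimises it optically).
    """

    image_shape: Tuple[int, int] = (1024, 1024)
    bit_depth: int = 16
    background_mean: Tuple[float, float, float, float] = (300.0, 300.0, 300.0, 300.0)
    background_sd: Tuple[float, float, float, float] = (30.0, 30.0, 30.0, 30.0)
    speckle_count: int = 30
    speckle_amplitude: Tuple[float, float] = (2000.0, 8000.0)
    speckle_radius: Tuple[float, float] = (1.0, 2.5)
    poisson_noise: bool = True
    read_noise_sd: float = 10.0
    min_gap: float = 3.0
    border_margin: int = 4
    max_place_tries: int = 10000
    background_window: int = 64

    def quiet(self) -> "RenderParams":
        """A noiseless, background-free variant (rendering-fidelity oracle)."""
        return replace(
            self,
            background_mean=(0.0,) * 4,
            background_sd=(0.0,) * 4,
            speckle_count=0,
            poisson_noise=False,
            read_noise_sd=0.0,
        )


@dataclass
class SyntheticGroundTruth:
    """What was actually painted into a rendered section."""

    label_mask: np.ndarray  # 0 = background, k = cell k
    cells: pd.DataFrame
    background_region: Tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    config_hash: str
    seed: int


def _place_cells(
    cells: Sequence[TrueCellState],
    params: RenderParams,
    rng: np.random.Generator,
) -> List[TrueCellState]:
    """Rejection-sample non-overlapping disk centers inside the usable field."""
    H, W = params.image_shape
    placed: List[TrueCellState] = []
    centers = np.empty((0, 2))
    radii = np.empty(0)
    for cell in cells:
        r = cell.radius
        lo_r, hi_r = r + params.border_margin, H - r - params.border_margin
        lo_c, hi_c = r + params.border_margin, W - r - params.border_margin
        if lo_r >= hi_r or lo_c >= hi_c:
            raise PlacementError(f"cell radius {r:.1f} px does not fit the field")
        for _ in range(params.max_place_tries):
            cand = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
            if centers.size:
                d = np.hypot(*(centers - cand).T)
                if np.any(d <= radii + r + params.min_gap):
                    continue
            centers = np.vstack([centers, cand])
            radii = np.append(radii, r)
            placed.append(replace(cell, center=(float(cand[0]), float(cand[1]))))
            break
        else:
            raise PlacementError(
                f"could not place cell {cell.cell_id} after "
                f"{params.max_place_tries} tries; reduce density or image load"
            )
    return placed


def _find_background_region(
    placed: Sequence[TrueCellState], params: RenderParams
) -> Tuple[int, int, int, int]:
    """First (row-major) cell-free window — the 'non-stained area' an analyst
    would pick for background estimation.  Falls back to smaller windows (down
    to 16 px) on crowded fields."""
    H, W = params.image_shape
    centers = np.array([c.center for c in placed]) if placed else np.empty((0, 2))
    radii = np.array([c.radius for c in placed])
    w = params.background_window
    sizes = []
    while w >= 16:
        sizes.append(w)
        w = (3 * w) // 4
    for w in sizes:
        for r0 in range(0, H - w + 1, max(w // 2, 1)):
            for c0 in range(0, W - w + 1, max(w // 2, 1)):
                if centers.size:
                    near_r = (centers[:, 0] > r0 - radii - 1) & (centers[:, 0] < r0 + w + radii + 1)
                    near_c = (centers[:, 1] > c0 - radii - 1) & (centers[:, 1] < c0 + w + radii + 1)
                    if np.any(near_r & near_c):
                        continue
                return (r0, c0, r0 + w, c0 + w)
    raise PlacementError("no cell-free background window found; image too crowded")


def _paint_disk(img: np.ndarray, row: float, col: float, radius: float, values: np.ndarray):
    """Add ``values`` (len-4) to all pixels within ``radius`` of the center;
    returns the boolean footprint (within the bounding box coordinates)."""
    H, W = img.shape[:2]
    r0, r1 = max(0, int(np.floor(row - radius))), min(H, int(np.ceil(row + radius)) + 1)
    c0, c1 = max(0, int(np.floor(col - radius))), min(W, int(np.ceil(col + radius)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
    img[r0:r1, c0:c1][inside] += values
    return inside, (r0, r1, c0, c1)


def _config_hash(params: RenderParams, extra: Dict) -> str:
    payload = {"render": asdict(params), **extra}
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def render_section(
    population: Sequence[TrueCellState],
    params: Optional[RenderParams] = None,
    *,
    crosstalk=None,
    seed: int = 0,
    subject_id: str = "synthetic",
    group_label: str = "control",
    run_id: int = 1,
    section_id: int = 1,
) -> Tuple[SectionImage, SyntheticGroundTruth]:
    """Render one 4-channel section image plus exact ground truth.

    Order of effects: disk painting on the background field, autofluorescence
    speckle, linear channel mixing by the crosstalk matrix (identity if
    ``crosstalk`` is None), Poisson shot noise, Gaussian read noise, clipping
    to bit depth.  The label mask marks exactly the painted disk pixels.
    """
    params = params or RenderParams()
    H, W = params.image_shape
    ceiling = 2**params.bit_depth - 1
    rng = np.random.default_rng(seed)

    placed = _place_cells(population, params, rng)
    bg_region = _find_background_region(placed, params)

    mu = np.asarray(params.background_mean, dtype=float)
    sd = np.asarray(params.background_sd, dtype=float)
    if np.any(sd > 0):
        img = mu + rng.standard_normal((H, W, 4)) * sd
    else:
        img = np.broadcast_to(mu, (H, W, 4)).copy()

    label_mask = np.zeros((H, W), dtype=np.uint16)
    for cell in placed:
        row, col = cell.center
        values = np.array([cell.expected[m] for m in MARKERS])
        inside, (r0, r1, c0, c1) = _paint_disk(img, row, col, cell.radius, values)
        label_mask[r0:r1, c0:c1][inside] = cell.cell_id

    # broadband autofluorescence grains (residual lipofuscin); the chosen
    # background window is kept clean, as an analyst would choose it
    br0, bc0, br1, bc1 = bg_region
    for _ in range(params.speckle_count):
        for _ in range(1000):
            row, col = rng.uniform(0, H), rng.uniform(0, W)
            if not (br0 - 3 <= row < br1 + 3 and bc0 - 3 <= col < bc1 + 3):
                break
        radius = rng.uniform(*params.speckle_radius)
        amp = rng.uniform(*params.speckle_amplitude)
        _paint_disk(img, row, col, radius, np.full(4, amp))

    if crosstalk is not None:
        A = np.asarray(getattr(crosstalk, "matrix", crosstalk), dtype=float)
        if A.shape != (4, 4):
            raise ValidationError("crosstalk matrix must be 4 x 4")
        img = img @ A.T

    if params.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if params.read_noise_sd > 0:
        img = img + rng.standard_normal((H, W, 4)) * params.read_noise_sd

    n_over = int(np.count_nonzero(img > ceiling))
    if n_over:
        warnings.warn(
            f"{n_over} pixel values exceeded the {params.bit_depth}-bit ceiling "
            "before clipping",
            stacklevel=2,
        )
    pixels = np.rint(np.clip(img, 0, ceiling)).astype(np.uint16)

    cells_df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in placed],
            "row": [c.center[0] for c in placed],
            "col": [c.center[1] for c in placed],
            "radius": [c.radius for c in placed],
            **{f"expected_{m.lower()}": [c.expected[m] for c in placed] for m in MARKERS},
            "deficient_ci": [c.deficient_ci for c in placed],
            "deficient_civ": [c.deficient_civ for c in placed],
        }
    )
    gt = SyntheticGroundTruth(
        label_mask=label_mask,
        cells=cells_df,
        background_region=bg_region,
        config_hash=_config_hash(params, {"n_cells": len(placed)}),
        seed=seed,
    )
    image = SectionImage(
        pixels=pixels,
        subject_id=subject_id,
        group_label=group_label,
        run_id=run_id,
        section_id=section_id,
        bit_depth=params.bit_depth,
    )
    return image, gt


def _child_seed(master_seed: int, *key: int) -> int:
    """Deterministic sub-seed, kept below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_cohort(
    profiles: Sequence[PatientProfile],
    seed: int,
    output_dir,
    *,
    render_params: Optional[RenderParams] = None,
    crosstalk=None,
) -> pd.DataFrame:
    """Simulate and write a full multi-run cohort dataset.

    For every run and subject, ``sections_per_run`` section images are
    rendered and written as multi-channel TIFF together with a label-mask
    TIFF, a ground-truth cell table (CSV), a cohort manifest (CSV) and a YAML
    echo of the full configuration.  Per-section seeds derive deterministically
    from the master seed, so identical calls are byte-identical on disk.

    Returns the manifest as a DataFrame (paths relative to ``output_dir``).
    """
    from . import imgio  # local import: imgio depends on channels only

    params = render_params or RenderParams()
    out = Path(output_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)

    groups = [p.group_label for p in profiles]
    if len(set(groups)) != len(groups):
        raise ValidationError("profiles must have distinct group labels")

    rows = []
    n_runs = max(p.runs for p in profiles)
    for run in range(1, n_runs + 1):
        for si, profile in enumerate(profiles):
            if run > profile.runs:
                continue
            subject = profile.group_label
            for sec in range(1, profile.sections_per_run + 1):
                pop_seed = _child_seed(seed, si, run, sec, 0)
                render_seed = _child_seed(seed, si, run, sec, 1)
                population = generate_cell_population(
                    profile, profile.cells_per_section, pop_seed
                )
                image, gt = render_section(
                    population,
                    params,
                    crosstalk=crosstalk,
                    seed=render_seed,
                    subject_id=subject,
                    group_label=profile.group_label,
                    run_id=run,
                    section_id=sec,
                )
                stem = f"{subject}_run{run}_sec{sec}"
                img_path = f"images/{stem}.tif"
                mask_path = f"truth/{stem}_mask.tif"
                cells_path = f"truth/{stem}_cells.csv"
                imgio.write_section_image(image, out / img_path)
                imgio.write_label_mask(gt.label_mask, out / mask_path)
                gt.cells.to_csv(out / cells_path, index=False)
                r0, c0, r1, c1 = gt.background_region
                rows.append(
                    {
                        "subject": subject,
                        "group": profile.group_label,
                        "run": run,
                        "section": sec,
                        "image": img_path,
                        "mask": mask_path,
                        "cells": cells_path,
                        "bg_r0": r0,
                        "bg_c0": c0,
                        "bg_r1": r1,
                        "bg_c1": c1,
                        "pop_seed": pop_seed,
                        "render_seed": render_seed,
                    }
                )

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    config = {
        "master_seed": int(seed),
        "render": asdict(params),
        "profiles": [asdict(p) for p in profiles],
        "channel_order": list(MARKERS),
        "baseline_medians": BASELINE_MEDIANS,
        "deficient_level_fraction": DEFICIENT_LEVEL_FRACTION,
        "shared_dispersion_fraction": SHARED_DISPERSION_FRACTION,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return manifest
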