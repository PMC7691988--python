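"""Synthetic micropatterned single-cell images and FRAP traces.

The generator emulates the experimental system this package analyses:
single
cells confined to square or rectangular fibronectin micropatterns
(areas 500-1800 um^2, aspect ratios 1:1, 1:5, 1:8), imaged in four
channels (fibronectin pattern, DNA stain, marker of interest, F-actin
cell fill), with a marker whose nuclear:cytoplasmic partition
coefficient ``rho`` is known ground truth.  ``rho = 1`` models a freely
diffusing control protein (eGFP-like); larger ``rho`` models nuclear
enrichment.  FRAP traces come from a two-pool first-order exchange
model between nucleus and cytoplasm with whole-compartment bleaching.

Every operation is deterministic given its seed; cohort cells draw
their seeds from one master seed by ``numpy.random.SeedSequence``
spawning, so a cohort is reproducible bit for bit.
"""

from __future__ import annotations

import csv
import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import MultiChannelImage, write_tiff
from .kinetics import FrapTrace
from .segment import CompartmentMasks, make_compartments

__all__ = [
    "MicropatternSpec",
    "CellSimParams",
    "GroundTruth",
    "FrapSimParams",
    "PatternGeometry",
    "SimulatedCell",
    "make_pattern_geometry",
    "simulate_cell_image",
    "simulate_cohort",
    "simulate_frap_trace",
    "write_cohort",
    "write_frap_trace",
]

#: z-profile of the synthetic 5-plane confocal mode; sums to 1 so the
#: z-summed stack reproduces the single-plane expectation.
ZSTACK_WEIGHTS = (0.10, 0.20, 0.40, 0.20, 0.10)


@dataclass(frozen=True)
class MicropatternSpec:
    """Geometry of one fibronectin micropattern.

    ``area`` is in um^2; ``aspect_ratio`` is long/short side (1 for a
    square; 5 and 8 are the usual elongated rectangles).  ``pixel_size`` is
    um/px (default 0.4, a 20x objective regime); ``image_margin`` is the
    background border, in pixels, around the pattern.
    """

    shape: str
    area: float
    aspect_ratio: float = 1.0
    pixel_size: float = 0.4
    image_margin: int = 16

    def __post_init__(self) -> None:
        if self.shape not in ("square", "rectangle"):
            raise ValueError(f"shape must be 'square' or 'rectangle', got {self.shape!r}")
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1 (long/short convention)")
        if self.shape == "square" and not math.isclose(self.aspect_ratio, 1.0):
            raise ValueError("a square has aspect_ratio 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.image_margin < 1:
            raise ValueError("image_margin must be >= 1 pixel")

    @property
    def side_lengths_um(self) -> tuple[float, float]:
        """(short, long) side lengths in um."""
        short = math.sqrt(self.area / self.aspect_ratio)
        return short, short * self.aspect_ratio


@dataclass(frozen=True)
class PatternGeometry:
    """Rendered pattern mask plus the physical geometry it encodes."""

    mask: np.ndarray
    side_lengths_um: tuple[float, float]
    frame_shape: tuple[int, int]
    pixel_size: float


@dataclass(frozen=True)
class CellSimParams:
    """Photometric parameters of one simulated cell.

    ``partition_coefficient`` (rho) is the nucleus:cytoplasm marker
    concentration ratio; 1 models free diffusion.  ``coloc_mixing``
    (None disables the second marker channel) sets the fraction of the
    second marker's spatial signal copied from the first: 0 gives two
    independent textures, 1 an affine copy.  Textured markers are only
    rendered when a second channel is requested; plain partition
    experiments use flat compartment intensities.  Noise follows a
    standard camera model: Poisson shot noise on the expected photon
    image, then additive Gaussian read noise.
    """

    partition_coefficient: float = 1.0
    nucleus_area_fraction: float = 0.25
    channel_brightness: Mapping[str, float] = field(
        default_factory=lambda: {
            "pattern": 150.0,
            "dna": 300.0,
            "marker": 200.0,
            "marker2": 200.0,
            "actin": 150.0,
        }
    )
    coloc_mixing: float | None = None
    texture_strength: float = 0.4
    texture_scale_um: float = 1.2
    shot_noise: bool = True
    read_noise_sigma: float = 2.0
    blur_sigma: float = 0.0
    zstack: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.partition_coefficient <= 0:
            raise ValueError("partition_coefficient must be positive")
        if not 0 < self.nucleus_area_fraction < 1:
            raise ValueError("nucleus_area_fraction must be in (0, 1)")
        if any(b <= 0 for b in self.channel_brightness.values()):
            raise ValueError("channel brightness values must be positive")
        if self.coloc_mixing is not None and not 0 <= self.coloc_mixing <= 1:
            raise ValueError("coloc_mixing must be in [0, 1]")
        if self.read_noise_sigma < 0:
            raise ValueError("read_noise_sigma must be >= 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless truth for one simulated cell."""

    masks: CompartmentMasks
    true_rho: float
    true_area: float
    true_aspect_ratio: float


@dataclass(frozen=True)
class FrapSimParams:
    """Two-pool exchange FRAP scenario.

    ``k_in`` (cytoplasm -> nucleus import) and ``k_out`` (export) are
    first-order rates in 1/s.  Bleaching multiplies the chosen
    compartment by ``bleach_residual`` at t = 0.  ``trace_noise_sigma``
    is Gaussian noise as a fraction of each compartment's pre-bleach
    intensity.
    """

    k_in: float
    k_out: float
    bleach_target: str = "nucleus"
    bleach_residual: float = 0.0
    duration: float = 120.0
    dt: float = 0.5
    pre_bleach_time: float = 5.0
    trace_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_in < 0 or self.k_out < 0:
            raise ValueError("rates must be >= 0")
        if self.bleach_target not in ("nucleus", "cytoplasm"):
            raise ValueError("bleach_target must be 'nucleus' or 'cytoplasm'")
        if not 0 <= self.bleach_residual < 1:
            raise ValueError("bleach_residual must be in [0, 1)")
        if self.dt <= 0 or self.dt >= self.duration:
            raise ValueError("require 0 < dt < duration")
        if self.pre_bleach_time < 2 * self.dt:
            raise ValueError("need at least two pre-bleach samples")


@dataclass(frozen=True)
class SimulatedCell:
    """One cohort member with its provenance."""

    cell_id: str
    geometry_label: str
    image: MultiChannelImage
    truth: GroundTruth
    seed: int


def make_pattern_geometry(
    spec: MicropatternSpec, frame_shape: tuple[int, int] | None = None
) -> PatternGeometry:
    """Render the filled, centred, axis-aligned pattern rectangle.

    The long side runs along columns.  Side lengths are rounded to whole
    pixels independently, keeping the mask area within ~2% of the
    requested area at the default pixel size.
    """
    short_um, long_um = spec.side_lengths_um
    n_rows = max(1, round(short_um / spec.pixel_size))
    n_cols = max(1, round(long_um / spec.pixel_size))
    if frame_shape is None:
        frame_shape = (n_rows + 2 * spec.image_margin, n_cols + 2 * spec.image_margin)
    h, w = frame_shape
    if n_rows > h - 2 or n_cols > w - 2:
        raise ValueError(
            f"pattern ({n_rows} x {n_cols} px) does not fit in frame {frame_shape}; "
            f"requires at least ({n_rows + 2}, {n_cols + 2})"
        )
    mask = np.zeros(frame_shape, dtype=bool)
    r0, c0 = (h - n_rows) // 2, (w - n_cols) // 2
    mask[r0 : r0 + n_rows, c0 : c0 + n_cols] = True
    return PatternGeometry(
        mask=mask,
        side_lengths_um=(short_um, long_um),
        frame_shape=frame_shape,
        pixel_size=spec.pixel_size,
    )


def _nucleus_ellipse(pattern: PatternGeometry, area_fraction: float) -> np.ndarray:
    """Concentric ellipse, same orientation as the pattern, with
    area = area_fraction x pattern area."""
    mask = pattern.mask
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    n_rows, n_cols = rows.size, cols.size
    cr = rows[0] + n_rows / 2
    cc = cols[0] + n_cols / 2
    # Semi-axes proportional to the rectangle sides, scaled to the area.
    scale = math.sqrt(4 * area_fraction / math.pi)
    a_r, a_c = scale * n_rows / 2, scale * n_cols / 2
    rr, cci = np.indices(mask.shape)
    ellipse = ((rr + 0.5 - cr) / a_r) ** 2 + ((cci + 0.5 - cc) / a_c) ** 2 <= 1.0
    if not ellipse.any() or (ellipse & ~mask).any():
        raise SegmentationConsistencyError(
            "nucleus ellipse is empty or not strictly inside the cell"
        )
    return ellipse


class SegmentationConsistencyError(RuntimeError):
    """Internal inconsistency while rendering ground-truth geometry."""


def _texture_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    strength: float,
    scale_px: float,
) -> np.ndarray:
    """Smooth multiplicative texture with mean ~1 (clipped at 0)."""
    if strength == 0:
        return np.ones(shape)
    z = gaussian_filter(rng.standard_normal(shape), scale_px)
    sd = z.std()
    if sd > 0:
        z /= sd
    return np.clip(1.0 + strength * z, 0.0, None)


def simulate_cell_image(
    spec: MicropatternSpec, params: CellSimParams
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one micropatterned cell.

    Channels: ``pattern`` (fibronectin print), ``dna`` (nonzero only in
    the nucleus), ``marker`` (expected intensity brightness*rho in the
    nucleus, brightness in the cytoplasm, 0 outside the cell), ``actin``
    (cell fill), plus ``marker2`` when ``coloc_mixing`` is set.  The
    expected image is optionally blurred, then shot and read noise are
    applied.  The returned :class:`GroundTruth` holds the noiseless
    masks and the true partition coefficient.
    """
    pattern = make_pattern_geometry(spec)
    cell = pattern.mask
    nucleus = _nucleus_ellipse(pattern, params.nucleus_area_fraction)
    masks = make_compartments(cell, nucleus, spec.pixel_size)
    rho = params.partition_coefficient
    b = params.channel_brightness
    rng = np.random.default_rng(params.seed)

    marker_base = b["marker"] * (rho * nucleus + 1.0 * masks.cytoplasm)
    expected: dict[str, np.ndarray] = {
        "pattern": b["pattern"] * cell.astype(float),
        "dna": b["dna"] * nucleus.astype(float),
        "marker": marker_base,
        "actin": b["actin"] * cell.astype(float),
    }
    if params.coloc_mixing is not None:
        scale_px = params.texture_scale_um / spec.pixel_size
        tex_a = _texture_field(rng, cell.shape, params.texture_strength, scale_px)
        tex_b = _texture_field(rng, cell.shape, params.texture_strength, scale_px)
        mix = params.coloc_mixing
        expected["marker"] = marker_base * tex_a
        expected["marker2"] = (
            b["marker2"] / b["marker"] * marker_base * (mix * tex_a + (1 - mix) * tex_b)
        )

    if params.blur_sigma > 0:
        sigma_px = params.blur_sigma / spec.pixel_size
        expected = {k: gaussian_filter(v, sigma_px) for k, v in expected.items()}

    channels: dict[str, np.ndarray] = {}
    for name, exp in expected.items():
        planes = (
            [w * exp for w in ZSTACK_WEIGHTS] if params.zstack else [exp]
        )
        noisy_planes = []
        for plane in planes:
            out = plane
            if params.shot_noise:
                out = rng.poisson(out).astype(float)
            if params.read_noise_sigma > 0:
                out = out + rng.normal(0.0, params.read_noise_sigma, plane.shape)
            noisy_planes.append(out)
        channels[name] = noisy_planes[0] if len(noisy_planes) == 1 else np.stack(noisy_planes)

    image = MultiChannelImage(
        channels=channels,
        pixel_size=spec.pixel_size,
        metadata={"true_rho": rho, "seed": params.seed},
    )
    truth = GroundTruth(
        masks=masks,
        true_rho=rho,
        true_area=float(cell.sum()) * spec.pixel_size**2,
        true_aspect_ratio=spec.aspect_ratio,
    )
    return image, truth


def _as_geometry_map(
    geometries: Mapping[str, MicropatternSpec] | Sequence[MicropatternSpec],
) -> dict[str, MicropatternSpec]:
    if isinstance(geometries, Mapping):
        return dict(geometries)
    out: dict[str, MicropatternSpec] = {}
    for spec in geometries:
        label = f"{spec.shape}{spec.aspect_ratio:g}_{spec.area:g}"
        if label in out:
            raise ValueError(f"duplicate geometry label {label!r}; pass a mapping")
        out[label] = spec
    return out


def simulate_cohort(
    geometries: Mapping[str, MicropatternSpec] | Sequence[MicropatternSpec],
    n_per_geometry: int,
    params: CellSimParams,
    rho_by_geometry: Mapping[str, float] | None = None,
    master_seed: int = 0,
) -> list[SimulatedCell]:
    """Simulate ``n_per_geometry`` cells for each pattern geometry.

    Per-cell seeds are spawned deterministically from ``master_seed``
    (one ``SeedSequence`` child per cell, in geometry-then-index order),
    so equal master seeds give bitwise-identical cohorts.
    ``rho_by_geometry`` overrides the partition coefficient per label.
    """
    geo = _as_geometry_map(geometries)
    if not geo:
        raise ValueError("geometry list is empty")
    if n_per_geometry < 1:
        raise ValueError("n_per_geometry must be >= 1")
    rho_by_geometry = dict(rho_by_geometry or {})
    unknown = set(rho_by_geometry) - set(geo)
    if unknown:
        raise ValueError(f"rho_by_geometry references unknown geometries: {unknown}")
    children = np.random.SeedSequence(master_seed).spawn(len(geo) * n_per_geometry)
    cells: list[SimulatedCell] = []
    i = 0
    for label, spec in geo.items():
        rho = rho_by_geometry.get(label, params.partition_coefficient)
        for j in range(n_per_geometry):
            seed = int(children[i].generate_state(1)[0])
            i += 1
            cell_params = dataclasses.replace(
                params, partition_coefficient=rho, seed=seed
            )
            image, truth = simulate_cell_image(spec, cell_params)
            cells.append(
                SimulatedCell(
                    cell_id=f"{label}_{j:04d}",
                    geometry_label=label,
                    image=image,
                    truth=truth,
                    seed=seed,
                )
            )
    return cells


def simulate_frap_trace(p: FrapSimParams) -> FrapTrace:
    """FRAP trace from the two-pool exchange model.

    Pools obey df_n/dt = k_in f_c - k_out f_n and df_c/dt = -df_n/dt,
    starting at the pre-bleach steady state f_n/f_c = k_in/k_out with
    total 1.  The bleach multiplies the target pool by
    ``bleach_residual`` at t = 0; afterwards the nuclear signal relaxes
    exponentially with rate k_in + k_out toward the new equilibrium and
    total fluorescence is conserved (no acquisition photobleaching).
    """
    k = p.k_in + p.k_out
    if k == 0:
        fn0 = fc0 = 0.5
        if p.bleach_residual < 1:
            warnings.warn(
                "k_in = k_out = 0: no exchange, no recovery possible; "
                "returning a flat post-bleach trace",
                stacklevel=2,
            )
    else:
        fn0, fc0 = p.k_in / k, p.k_out / k
    n_pre = round(p.pre_bleach_time / p.dt)
    n_post = round(p.duration / p.dt)
    time = (np.arange(n_pre + n_post + 1) - n_pre) * p.dt
    post = time >= 0
    fn = np.full(time.shape, fn0)
    fc = np.full(time.shape, fc0)
    if p.bleach_target == "nucleus":
        fn_b, fc_b = fn0 * p.bleach_residual, fc0
    else:
        fn_b, fc_b = fn0, fc0 * p.bleach_residual
    total = fn_b + fc_b
    if k > 0:
        fn_inf = total * p.k_in / k
        fn[post] = fn_inf + (fn_b - fn_inf) * np.exp(-k * time[post])
    else:
        fn[post] = fn_b
    fc[post] = total - fn[post]
    if p.trace_noise_sigma > 0:
        rng = np.random.default_rng(p.seed)
        fn = fn + rng.normal(0.0, p.trace_noise_sigma * fn0, fn.shape)
        fc = fc + rng.normal(0.0, p.trace_noise_sigma * fc0, fc.shape)
    return FrapTrace(
        time=time,
        nuclear_intensity=fn,
        cytoplasmic_intensity=fc,
        bleach_index=n_pre,
        bleach_target=p.bleach_target,
    )


def write_cohort(cells: Iterable[SimulatedCell], outdir: str | Path) -> Path:
    """Write one multi-page TIFF per cell plus a ground-truth manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["cell_id", "geometry", "area_um2", "aspect_ratio", "true_rho", "seed", "file"]
        )
        for cell in cells:
            fname = f"{cell.cell_id}.tiff"
            write_tiff(cell.image, outdir / fname)
            writer.writerow(
                [
                    cell.cell_id,
                    cell.geometry_label,
                    f"{cell.truth.true_area:.4f}",
                    f"{cell.truth.true_aspect_ratio:g}",
                    f"{cell.truth.true_rho:g}",
                    cell.seed,
                    fname,
                ]
            )
    return manifest


def write_frap_trace(trace: FrapTrace, path: str | Path) -> Path:
    """Write a trace as CSV: time_s, nuclear_mean, cytoplasmic_mean, bleach_frame."""
    path = Path(path)
    cyto = (
        trace.cytoplasmic_intensity
        if trace.cytoplasmic_intensity is not None
        else np.full_like(trace.time, np.nan)
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "nuclear_mean", "cytoplasmic_mean", "bleach_frame"])
        for t, n, c in zip(trace.time, trace.nuclear_intensity, cyto):
            writer.writerow([repr(float(t)), repr(float(n)), repr(float(c)), trace.bleach_index])
    return path
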