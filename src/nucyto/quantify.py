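"""Per-cell readouts: N/C ratio, totals, z-projection, colocalisation.

The central statistic is the nuclear:cytoplasmic ratio

    nc_ratio = <I_Nuc> / <I_Cyto>

i.e. mean background-subtracted marker intensity per nuclear pixel
divided by the mean per cytoplasmic pixel.  Colocalisation between two
markers is the Pearson correlation of their pixel intensities computed
separately over the nucleus and the cytoplasm of one characteristic
plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .segment import CompartmentMasks, shape_metrics

__all__ = [
    "CellMeasurement",
    "ColocResult",
    "zstack_project_sum",
    "estimate_background",
    "nc_ratio",
    "compartment_pearson",
]


@dataclass(frozen=True)
class CellMeasurement:
    """One cell's intensity and shape summary."""

    mean_nuc: float
    mean_cyto: float
    nc_ratio: float
    total_intensity: float
    area: float
    aspect_ratio: float
    geometry_label: str = ""
    cell_id: str = ""


@dataclass(frozen=True)
class ColocResult:
    """Compartment-wise Pearson coefficients; NaN where a channel is
    constant within the compartment (flagged, never reported as 0)."""

    pearson_nucleus: float
    pearson_cytoplasm: float
    n_nucleus: int
    n_cytoplasm: int

    @property
    def nucleus_defined(self) -> bool:
        return not np.isnan(self.pearson_nucleus)

    @property
    def cytoplasm_defined(self) -> bool:
        return not np.isnan(self.pearson_cytoplasm)


def zstack_project_sum(stack: np.ndarray) -> np.ndarray:
    """Pixel-wise sum of the planes of a z-stack.

    A single 2-D plane is returned unchanged; planes must share one
    shape.  Used for small-depth-of-focus confocal acquisitions, where
    compartment intensities are measured on the z-summed image.
    """
    if isinstance(stack, np.ndarray) and stack.ndim == 2:
        return stack
    planes = [np.asarray(p, dtype=float) for p in stack]
    if not planes:
        raise ValueError("empty z-stack")
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError(f"plane shapes differ: {[p.shape for p in planes]}")
    return np.sum(planes, axis=0)


def estimate_background(channel: np.ndarray, masks: CompartmentMasks) -> float:
    """Median intensity outside the cell mask (robust to stray signal)."""
    outside = ~masks.cell
    if not outside.any():
        return 0.0
    # read noise is zero-mean, so a slightly negative median means "no
    # background"; clip rather than subtracting a negative offset
    return max(0.0, float(np.median(np.asarray(channel, dtype=float)[outside])))


def nc_ratio(
    marker_channel: np.ndarray,
    masks: CompartmentMasks,
    background: float | None = None,
    geometry_label: str = "",
    cell_id: str = "",
) -> CellMeasurement:
    """Nuclear:cytoplasmic ratio of a marker channel.

    ``background`` defaults to the median intensity outside the cell;
    pass a constant (>= 0) to override.  Intensities are background-
    subtracted and clipped at zero before averaging; the total is the
    subtracted sum over the whole cell mask.
    """
    marker = np.asarray(marker_channel, dtype=float)
    if marker.ndim == 3:
        marker = zstack_project_sum(marker)
    if marker.shape != masks.cell.shape:
        raise ValueError("marker channel and masks have different shapes")
    if background is None:
        background = estimate_background(marker, masks)
    if background < 0:
        raise ValueError("background must be >= 0")
    sub = np.clip(marker - background, 0.0, None)
    mean_nuc = float(sub[masks.nucleus].mean())
    mean_cyto = float(sub[masks.cytoplasm].mean())
    if mean_cyto == 0:
        raise ZeroDivisionError(
            "undefined N/C ratio: cytoplasmic mean is 0 after background subtraction"
        )
    metrics = shape_metrics(masks.cell, masks.pixel_size)
    return CellMeasurement(
        mean_nuc=mean_nuc,
        mean_cyto=mean_cyto,
        nc_ratio=mean_nuc / mean_cyto,
        total_intensity=float(sub[masks.cell].sum()),
        area=metrics.area,
        aspect_ratio=metrics.aspect_ratio,
        geometry_label=geometry_label,
        cell_id=cell_id,
    )


def _masked_pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    x, y = a[mask], b[mask]
    if x.size < 2:
        raise ValueError("compartment has fewer than 2 pixels")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), int(x.size)
    r, _ = sps.pearsonr(x, y)
    return float(r), int(x.size)


def compartment_pearson(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    masks: CompartmentMasks,
    background_a: float = 0.0,
    background_b: float = 0.0,
) -> ColocResult:
    """Pearson correlation of two channels, per compartment.

    Computed on raw intensities of one characteristic plane by default
    (Pearson is invariant to the constant offset background subtraction
    would remove); pass backgrounds to subtract first.  A compartment
    where either channel is constant yields NaN, flagged via
    ``ColocResult.*_defined``.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.ndim == 3:
        a = zstack_project_sum(a)
    if b.ndim == 3:
        b = zstack_project_sum(b)
    if a.shape != b.shape or a.shape != masks.cell.shape:
        raise ValueError("channels and masks must share one shape")
    a = a - background_a
    b = b - background_b
    r_nuc, n_nuc = _masked_pearson(a, b, masks.nucleus)
    r_cyto, n_cyto = _masked_pearson(a, b, masks.cytoplasm)
    return ColocResult(
        pearson_nucleus=r_nuc,
        pearson_cytoplasm=r_cyto,
        n_nucleus=n_nuc,
        n_cytoplasm=n_cyto,
    )
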