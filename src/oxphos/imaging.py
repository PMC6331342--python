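"""Threshold-and-mask particle quantification for nuclear-foci readouts.

Mirrors a two-step ImageJ particle analysis on [0, 1]-scaled grayscale
fields: (1) cell counting at threshold 0.180, keeping particles with area
strictly above 80 px and circularity above 0.4; (2) nuclear-body (PML-NB)
counting at threshold 0.150, keeping particles of area 1-25 px with
circularity above 0.6.  The per-field readout is foci per cell.
Circularity is 4*pi*area/perimeter^2 (perimeter by the boundary line-
segment estimator of scikit-image), clamped to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

CELL_THRESHOLD = 0.180
CELL_MIN_AREA = 80  # strictly greater than
CELL_MIN_CIRCULARITY = 0.4

NB_THRESHOLD = 0.150
NB_AREA_RANGE = (1, 25)  # inclusive
NB_MIN_CIRCULARITY = 0.6


@dataclass(frozen=True)
class Particle:
    label: int
    area: int
    perimeter: float
    circularity: float
    centroid: tuple[float, float]


@dataclass(frozen=True)
class NbQuantResult:
    cell_count: int
    nb_count: int
    nb_per_cell: float | None  # None when cell_count == 0 (undefined, flagged)

    @property
    def undefined(self) -> bool:
        return self.nb_per_cell is None


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 1.0  # single-pixel / degenerate boundary: treat as round
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def detect_particles(
    img: np.ndarray,
    threshold: float,
    size_range: tuple[float, float] = (0, math.inf),
    circ_min: float = 0.0,
) -> list[Particle]:
    """Connected components of ``img > threshold`` passing size/circularity filters.

    Components use 8-connectivity (two discs touching diagonally are one
    particle).  ``size_range`` is inclusive on both ends; circularity is
    strict (``> circ_min``).
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("detect_particles expects a 2-D grayscale image")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    mask = img > threshold
    labeled = measure.label(mask, connectivity=2)
    particles = []
    lo, hi = size_range
    for region in measure.regionprops(labeled):
        area = int(region.area)
        if not (lo <= area <= hi):
            continue
        perim = float(region.perimeter)
        circ = _circularity(area, perim)
        if circ <= circ_min:
            continue
        particles.append(
            Particle(
                label=int(region.label),
                area=area,
                perimeter=perim,
                circularity=circ,
                centroid=tuple(float(c) for c in region.centroid),
            )
        )
    return particles


def count_cells(img: np.ndarray, threshold: float = CELL_THRESHOLD) -> int:
    """Cell count: particles with area > 80 px and circularity > 0.4."""
    parts = detect_particles(
        img,
        threshold=threshold,
        size_range=(CELL_MIN_AREA + 1, math.inf),  # "size > 80" is strict
        circ_min=CELL_MIN_CIRCULARITY,
    )
    return len(parts)


def count_nbs(img: np.ndarray, threshold: float = NB_THRESHOLD) -> int:
    """Nuclear-body count: particles of area 1-25 px with circularity > 0.6."""
    parts = detect_particles(
        img,
        threshold=threshold,
        size_range=NB_AREA_RANGE,
        circ_min=NB_MIN_CIRCULARITY,
    )
    return len(parts)


def nb_per_cell(nbs: int, cells: int) -> NbQuantResult:
    """Foci per cell; undefined (flagged, not silent) when there are no cells."""
    if cells < 0 or nbs < 0:
        raise ValueError("counts must be non-negative")
    ratio = None if cells == 0 else nbs / cells
    return NbQuantResult(cell_count=cells, nb_count=nbs, nb_per_cell=ratio)


def quantify_field(nuclei: np.ndarray, foci: np.ndarray) -> NbQuantResult:
    """Two-step quantification of a field: cells on one channel, NBs on the other."""
    return nb_per_cell(count_nbs(foci), count_cells(nuclei))


def hscore(intensity: float, percent_positive: float) -> float:
    """IHC histologic score: staining intensity (0-3) x percent positive cells."""
    if not (0 <= intensity <= 3):
        raise ValueError("intensity grade must be in [0, 3]")
    if not (0 <= percent_positive <= 100):
        raise ValueError("percent positive must be in [0, 100]")
    return intensity * percent_positive
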