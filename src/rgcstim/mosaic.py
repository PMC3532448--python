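"""RGC mosaics: jittered lattice placement and coverage factor.

A mosaic tiles copies of a template cell over a planar lattice with i.i.d.
Gaussian positional jitter (5 um SD for large-field cells, 1 um for midget
cells).  Spatial coverage is quantified by the dimensionless coverage factor,
density x mean dendritic-field area (Rodieck), with the dendritic field taken
as a circle of the mean field diameter; values below 1 indicate incomplete
coverage, 1-3 some overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology import Morphology

__all__ = ["PlacedCell", "Mosaic", "build_mosaic", "coverage_factor"]


@dataclass
class PlacedCell:
    cell_id: int
    offset: np.ndarray  # (2,) planar offset um

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=float)


@dataclass
class Mosaic:
    """Placed cells sharing a template morphology.

    ``extent`` is the tiled planar area in um^2 (lattice pitch times count),
    used for the density in the coverage factor.
    """

    template: Morphology
    cells: list = field(default_factory=list)
    extent: float = 0.0
    jitter_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("cell ids must be unique")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def density(self) -> float:
        if self.extent <= 0:
            raise ValueError("mosaic extent must be positive")
        return len(self.cells) / self.extent

    @property
    def mean_field_diameter(self) -> float:
        return self.template.dendritic_field_diameter()

    def offsets(self) -> np.ndarray:
        return np.array([c.offset for c in self.cells]).reshape(-1, 2)

    def placed(self, cell_id: int) -> Morphology:
        """Template translated to one cell's position."""
        cell = next(c for c in self.cells if c.cell_id == cell_id)
        return self.template.translated(cell.offset[0], cell.offset[1])

    def axon_polylines(self) -> dict:
        """In-plane axon polylines keyed by cell id."""
        base = self.template.axon_polyline()[:, :2]
        return {c.cell_id: base + c.offset for c in self.cells}

    def to_manifest(self, path, swc_path: str = "template.swc") -> None:
        df = pd.DataFrame({
            "cell_id": [c.cell_id for c in self.cells],
            "x_offset_um": [c.offset[0] for c in self.cells],
            "y_offset_um": [c.offset[1] for c in self.cells],
            "swc_path": swc_path,
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_manifest(cls, path, template: Morphology, extent: float) -> "Mosaic":
        df = pd.read_csv(path)
        cells = [PlacedCell(int(r.cell_id), (r.x_offset_um, r.y_offset_um))
                 for r in df.itertuples()]
        return cls(template=template, cells=cells, extent=extent)


def build_mosaic(template: Morphology, rows: int, cols: int, spacing: float,
                 jitter_sd: float = 5.0, seed: int = 0) -> Mosaic:
    """Tile rows x cols cells on a lattice with Gaussian planar jitter.

    The lattice is centered on the origin; the same seed always reproduces
    the same mosaic.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter SD must be non-negative")
    rng = np.random.default_rng(seed)
    cells = []
    x0 = -(cols - 1) * spacing / 2.0
    y0 = -(rows - 1) * spacing / 2.0
    cid = 0
    for r in range(rows):
        for c in range(cols):
            jitter = rng.normal(0.0, jitter_sd, 2) if jitter_sd > 0 else np.zeros(2)
            cells.append(PlacedCell(cid, np.array([x0 + c * spacing,
                                                   y0 + r * spacing]) + jitter))
            cid += 1
    return Mosaic(template=template, cells=cells,
                  extent=rows * cols * spacing ** 2,
                  jitter_sd=jitter_sd, seed=seed)


def coverage_factor(mosaic: Mosaic) -> float:
    """Density x mean dendritic-field area (circle of the mean diameter)."""
    if mosaic.extent <= 0:
        raise ValueError("mosaic extent must be positive")
    if len(mosaic) == 0:
        return 0.0
    d = mosaic.mean_field_diameter
    return mosaic.density * np.pi * (d / 2.0) ** 2
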