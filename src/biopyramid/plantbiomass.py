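"""Study-area plant biomass: totals, densities and the herbivore-available fraction.

Inputs are grid-cell (5 x 5 km) summaries of above-ground biomass (AGB,
tonnes per cell) and annual net primary productivity (NPP, tonnes per cell
per year), already aggregated from whatever remote-sensing products produced
them.  NPP serves as a proxy for the plant biomass actually available to
herbivores: per cell, the NPP values are averaged over years and divided by
the cell's AGB; the unweighted mean of those per-cell fractions times the
study-area AGB total gives the "available" biomass.  Cells with zero AGB are
excluded from the fraction average (the ratio is undefined) but still count
toward totals.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_STUDY_AREA_KM2 = 1125.0


@dataclass(frozen=True)
class CellPlantBiomass:
    cell_id: str
    agb_tonnes: float
    npp_annual_tonnes: tuple[float, ...]

    def __post_init__(self):
        if self.agb_tonnes < 0:
            raise InputError(f"cell {self.cell_id!r}: negative AGB")
        if not self.npp_annual_tonnes:
            raise InputError(f"cell {self.cell_id!r}: empty NPP series")
        if any(v < 0 for v in self.npp_annual_tonnes):
            raise InputError(f"cell {self.cell_id!r}: negative NPP value")

    @property
    def mean_npp(self) -> float:
        return float(np.mean(self.npp_annual_tonnes))


def read_cells_csv(path) -> list[CellPlantBiomass]:
    """Read cells from CSV; wide (`npp_2016,...`) is canonical, long accepted.

    Wide: ``cell_id,agb_tonnes,npp_<year>,...``.
    Long: ``cell_id,agb_tonnes,year,npp_tonnes`` (one row per cell-year).
    """
    df = pd.read_csv(path)
    if "cell_id" not in df.columns or "agb_tonnes" not in df.columns:
        raise InputError(f"cells file {path} needs cell_id and agb_tonnes columns")
    npp_cols = sorted(c for c in df.columns if c.startswith("npp_") and c != "npp_tonnes")
    cells = []
    if npp_cols:
        for _, row in df.iterrows():
            cells.append(
                CellPlantBiomass(
                    cell_id=str(row["cell_id"]),
                    agb_tonnes=float(row["agb_tonnes"]),
                    npp_annual_tonnes=tuple(float(row[c]) for c in npp_cols),
                )
            )
    elif {"year", "npp_tonnes"} <= set(df.columns):
        for cid, grp in df.groupby("cell_id", sort=True):
            agb = grp["agb_tonnes"].iloc[0]
            grp = grp.sort_values("year")
            cells.append(
                CellPlantBiomass(
                    cell_id=str(cid),
                    agb_tonnes=float(agb),
                    npp_annual_tonnes=tuple(grp["npp_tonnes"].astype(float)),
                )
            )
    else:
        raise InputError(f"cells file {path}: no npp_<year> columns and no year/npp_tonnes pair")
    return cells


def npp_fraction(cells: list[CellPlantBiomass], weighted: bool = False) -> float:
    """Mean across cells of (temporal-mean NPP) / AGB.

    Unweighted by default — every cell contributes equally regardless of its
    standing biomass; ``weighted=True`` switches to an AGB-weighted mean.
    Zero-AGB cells are excluded with a logged notice.
    """
    if not cells:
        raise InputError("empty cell list")
    included = [c for c in cells if c.agb_tonnes > 0]
    for c in cells:
        if c.agb_tonnes == 0:
            logger.info("cell %s: AGB is zero, excluded from the fraction average", c.cell_id)
    if not included:
        raise InputError("no cell with positive AGB")
    fracs = np.array([c.mean_npp / c.agb_tonnes for c in included])
    if weighted:
        w = np.array([c.agb_tonnes for c in included])
        return float(np.average(fracs, weights=w))
    return float(fracs.mean())


def available_biomass(total_agb_tonnes: float, mean_npp_fraction: float) -> float:
    """Plant biomass available for mammal consumption: fraction x total AGB."""
    if not 0.0 <= mean_npp_fraction <= 1.0:
        raise InputError(f"NPP fraction {mean_npp_fraction} outside [0, 1]")
    return total_agb_tonnes * mean_npp_fraction


def plant_densities(total_tonnes: float, study_area_km2: float = DEFAULT_STUDY_AREA_KM2) -> float:
    """Tonnes per km^2, full precision (the report layer prints integers)."""
    if study_area_km2 <= 0:
        raise InputError("study area must be positive")
    return total_tonnes / study_area_km2


@dataclass
class PlantSummary:
    total_agb_tonnes: float
    available_tonnes: float
    agb_density_t_km2: float
    available_density_t_km2: float
    mean_npp_fraction: float
    study_area_km2: float
    n_cells: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "PlantSummary":
        return cls(**json.loads(Path(path).read_text()))


def summarize_cells(
    cells: list[CellPlantBiomass],
    study_area_km2: float = DEFAULT_STUDY_AREA_KM2,
    weighted: bool = False,
) -> PlantSummary:
    """Totals, available fraction and densities for a set of grid cells."""
    total = float(sum(c.agb_tonnes for c in cells))
    frac = npp_fraction(cells, weighted=weighted)
    avail = available_biomass(total, frac)
    return PlantSummary(
        total_agb_tonnes=total,
        available_tonnes=avail,
        agb_density_t_km2=plant_densities(total, study_area_km2),
        available_density_t_km2=plant_densities(avail, study_area_km2),
        mean_npp_fraction=frac,
        study_area_km2=study_area_km2,
        n_cells=len(cells),
    )
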