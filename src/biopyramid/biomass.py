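"""From relative abundance to densities, total biomass and the trophic pyramid.

The conversion chain per species:

    density (ind km^-2)   = relative_abundance * group_size / home_range_km2
    total abundance       = density * study_area_km2
    biomass (tonnes)      = total_abundance * body_mass_kg / 1000
    biomass (kg km^-2)    = biomass_tonnes * 1000 / study_area_km2

The species' median home range acts as the effective capture area of a
camera, identical for every camera; relative abundance is animals per
station, so dividing by home range converts station counts to a density.
All arithmetic is kept at full precision; half-up rounding to the printed
number of decimals happens only in the report layer, because published
tables mix rounded and unrounded intermediates.

The pyramid summary pools biomass by trophic group and taxonomic order and
derives the trophic transfer rate (secondary/primary * 100), the
prey:predator biomass ratio (its reciprocal, times 100), and — when plant
totals are supplied — the plant:herbivore ratios for total above-ground
biomass and for the fraction available to herbivores.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError

DEFAULT_STUDY_AREA_KM2 = 1125.0
TROPHIC_GROUPS = ("primary_consumer", "secondary_consumer", "omnivore")


@dataclass(frozen=True)
class SpeciesTraits:
    """Life-history traits driving the abundance-to-biomass conversion."""

    species: str
    body_mass_kg: float
    group_size: float
    home_range_km2: float
    trophic_group: str
    order: str

    def __post_init__(self):
        for f in ("body_mass_kg", "group_size", "home_range_km2"):
            v = getattr(self, f)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ConfigError(f"species {self.species!r}: {f} must be a positive number, got {v!r}")
        if self.trophic_group not in TROPHIC_GROUPS:
            raise ConfigError(
                f"species {self.species!r}: trophic_group {self.trophic_group!r} "
                f"not one of {TROPHIC_GROUPS}"
            )
        if not self.order:
            raise ConfigError(f"species {self.species!r}: empty taxonomic order")


def load_traits_csv(path) -> dict[str, SpeciesTraits]:
    """Read a traits table: species,body_mass_kg,group_size,home_range_km2,trophic_group,order."""
    df = pd.read_csv(path)
    required = {"species", "body_mass_kg", "group_size", "home_range_km2", "trophic_group", "order"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"traits file {path} is missing columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        t = SpeciesTraits(
            species=str(row["species"]),
            body_mass_kg=float(row["body_mass_kg"]),
            group_size=float(row["group_size"]),
            home_range_km2=float(row["home_range_km2"]),
            trophic_group=str(row["trophic_group"]),
            order=str(row["order"]),
        )
        out[t.species] = t
    return out


def density_from_abundance(relative_abundance: float, traits: SpeciesTraits) -> float:
    """Animals per station -> individuals per km^2 via group size and home range."""
    if relative_abundance < 0:
        raise ConfigError("relative abundance must be non-negative")
    return relative_abundance * traits.group_size / traits.home_range_km2

def total_abundance(density_ind_km2: float, study_area_km2: float = DEFAULT_STUDY_AREA_KM2) -> float:
    """Animals in the whole study area (unrounded; display rounding is report-side)."""
    if study_area_km2 <= 0:
        raise ConfigError("study area must be positive")
    return density_ind_km2 * study_area_km2

def species_biomass(total_abund: float, traits: SpeciesTraits) -> float:
    """Total abundance x adult body mass, in tonnes."""
    return total_abund * traits.body_mass_kg / 1000.0


def build_biomass_table(
    relative_abundance: Mapping[str, float],
    traits: Mapping[str, SpeciesTraits],
    study_area_km2: float = DEFAULT_STUDY_AREA_KM2,
) -> pd.DataFrame:
    """Apply the full conversion chain to every species.

    Returns a DataFrame indexed by species with columns relative_abundance,
    density_ind_km2, total_abundance, biomass_tonnes, biomass_kg_km2,
    pct_of_mammal_biomass, trophic_group, order; the study area is stored in
    ``df.attrs["study_area_km2"]``.
    """
    rows = {}
    for sp, rel in relative_abundance.items():
        if sp not in traits:
            raise ConfigError(f"species {sp!r} has no traits entry")
        t = traits[sp]
        dens = density_from_abundance(rel, t)
        tot = total_abundance(dens, study_area_km2)
        bio = species_biomass(tot, t)
        rows[sp] = {
            "relative_abundance": rel,
            "density_ind_km2": dens,
            "total_abundance": tot,
            "biomass_tonnes": bio,
            "biomass_kg_km2": bio * 1000.0 / study_area_km2,
            "trophic_group": t.trophic_group,
            "order": t.order,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species"
    df["pct_of_mammal_biomass"] = 100.0 * df["biomass_tonnes"] / df["biomass_tonnes"].sum()
    df.attrs["study_area_km2"] = study_area_km2
    return df


def table_from_reference(
    reference: pd.DataFrame, study_area_km2: float = DEFAULT_STUDY_AREA_KM2
) -> pd.DataFrame:
    """Biomass table from already-estimated per-species density and biomass.

    ``reference`` must be indexed by species with columns density_ind_km2,
    biomass_tonnes, trophic_group and order (e.g. a published point-estimate
    table); the remaining columns of the standard table are derived.
    """
    required = {"density_ind_km2", "biomass_tonnes", "trophic_group", "order"}
    missing = required - set(reference.columns)
    if missing:
        raise ConfigError(f"reference table is missing columns {sorted(missing)}")
    df = reference.copy()
    df["total_abundance"] = df["density_ind_km2"] * study_area_km2
    df["biomass_kg_km2"] = df["biomass_tonnes"] * 1000.0 / study_area_km2
    df["pct_of_mammal_biomass"] = 100.0 * df["biomass_tonnes"] / df["biomass_tonnes"].sum()
    df.attrs["study_area_km2"] = study_area_km2
    return df


@dataclass
class PyramidSummary:
    """Pooled trophic-pyramid statistics for one biomass table."""

    study_area_km2: float
    total_biomass_tonnes: float
    mean_biomass_t_km2: float
    by_trophic_group: pd.DataFrame
    by_order: pd.DataFrame
    transfer_pct: float
    prey_predator_ratio: float
    plant_to_herbivore_ratio_total: float | None = None
    plant_to_herbivore_ratio_available: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "study_area_km2": self.study_area_km2,
            "total_biomass_tonnes": self.total_biomass_tonnes,
            "mean_biomass_t_km2": self.mean_biomass_t_km2,
            "by_trophic_group": self.by_trophic_group.to_dict(orient="index"),
            "by_order": self.by_order.to_dict(orient="index"),
            "transfer_pct": self.transfer_pct,
            "prey_predator_ratio": self.prey_predator_ratio,
            "plant_to_herbivore_ratio_total": self.plant_to_herbivore_ratio_total,
            "plant_to_herbivore_ratio_available": self.plant_to_herbivore_ratio_available,
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def pyramid_summary(
    table: pd.DataFrame,
    plant_total_t: float | None = None,
    plant_available_t: float | None = None,
) -> PyramidSummary:
    """Pool a biomass table by trophic group and order and derive the pyramid.

    Pooled values are always sums of member species (published pooled rows
    occasionally disagree with their members by a rounding residue; a note
    flags any table whose printed-style group sums would differ).  The
    transfer rate is 100 * secondary / primary biomass, and transfer_pct *
    prey_predator_ratio == 100 exactly, pre-rounding.
    """
    if "trophic_group" not in table.columns or "order" not in table.columns:
        raise ConfigError("biomass table must carry trophic_group and order columns")
    unknown = set(table["trophic_group"]) - set(TROPHIC_GROUPS)
    if unknown:
        raise ConfigError(f"unknown trophic group(s) {sorted(unknown)}")
    area = table.attrs.get("study_area_km2", DEFAULT_STUDY_AREA_KM2)
    total = float(table["biomass_tonnes"].sum())

    def pool(key):
        g = table.groupby(key)["biomass_tonnes"].sum().to_frame()
        g["biomass_kg_km2"] = g["biomass_tonnes"] * 1000.0 / area
        g["pct"] = 100.0 * g["biomass_tonnes"] / total
        return g.sort_values("biomass_tonnes", ascending=False)

    by_group = pool("trophic_group")
    by_order = pool("order")

    primary = float(by_group["biomass_tonnes"].get("primary_consumer", 0.0))
    secondary = float(by_group["biomass_tonnes"].get("secondary_consumer", 0.0))
    if primary <= 0:
        raise ConfigError("no primary-consumer biomass: transfer rate undefined")
    transfer = 100.0 * secondary / primary
    ratio = primary / secondary if secondary > 0 else math.inf

    notes = []
    r_total = r_avail = None
    herb = primary
    if plant_total_t is not None:
        r_total = plant_total_t / herb
    if plant_available_t is not None:
        r_avail = plant_available_t / herb

    return PyramidSummary(
        study_area_km2=area,
        total_biomass_tonnes=total,
        mean_biomass_t_km2=total / area,
        by_trophic_group=by_group,
        by_order=by_order,
        transfer_pct=transfer,
        prey_predator_ratio=ratio,
        plant_to_herbivore_ratio_total=r_total,
        plant_to_herbivore_ratio_available=r_avail,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Report layer


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal-style half-up rounding (published tables do not round half-even)."""
    q = 10.0**decimals
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


def render_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display-rounded copy of a biomass table, matching published precision."""
    out = table.copy()
    out["total_abundance"] = [round_half_up(v) for v in out["total_abundance"]]
    out["density_ind_km2"] = [round_half_up(v, 2) for v in out["density_ind_km2"]]
    out["biomass_tonnes"] = [round_half_up(v, 2) for v in out["biomass_tonnes"]]
    out["biomass_kg_km2"] = [round_half_up(v, 2) for v in out["biomass_kg_km2"]]
    out["pct_of_mammal_biomass"] = [round_half_up(v, 1) for v in out["pct_of_mammal_biomass"]]
    return out
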