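"""Bundled reference tables for the Cantabrian-range mammal survey.

Two kinds of data ship with the package:

* ``cantabrian_reference.csv`` — the published per-species point estimates
  (total abundance, density, biomass) for the 10-species Cantabrian
  camera-trap survey, used as arithmetic-consistency inputs: the raw camera
  records are not bundled, so species abundances are exercised downstream of
  estimation, not re-estimated.
* ``synthetic_traits.csv`` — a SYNTHETIC stand-in for the survey's species
  trait table (the original lives in supplementary material that is not
  redistributed here).  Group sizes and home ranges are field-plausible
  values and body masses are back-solved from the published table, so that
  the full conversion chain applied to the implied relative abundances
  reproduces the published densities and biomasses.
* ``cantabrian_plant_reference.json`` — published study-area plant totals
  (above-ground biomass and the NPP-based available fraction).
"""
from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .biomass import SpeciesTraits, load_traits_csv


def _data(name: str):
    return resources.files("biopyramid.data").joinpath(name)


def load_synthetic_traits() -> dict[str, SpeciesTraits]:
    """Synthetic trait table keyed by species (see module docstring)."""
    with resources.as_file(_data("synthetic_traits.csv")) as p:
        return load_traits_csv(p)


def load_reference_estimates() -> pd.DataFrame:
    """Published per-species point estimates, indexed by species."""
    with resources.as_file(_data("cantabrian_reference.csv")) as p:
        return pd.read_csv(p, index_col="species")


def load_reference_plants() -> dict:
    """Published study-area plant biomass totals."""
    return json.loads(_data("cantabrian_plant_reference.json").read_text())


def implied_relative_abundance(
    reference: pd.DataFrame | None = None,
    traits: dict[str, SpeciesTraits] | None = None,
    study_area_km2: float = 1125.0,
) -> dict[str, float]:
    """Back out per-species relative abundance (animals per station).

    Inverts the conversion chain using the published total abundance (the
    least-rounded printed quantity): density = abundance / area, then
    relative abundance = density * home_range / group_size.
    """
    reference = load_reference_estimates() if reference is None else reference
    traits = load_synthetic_traits() if traits is None else traits
    out = {}
    for sp, row in reference.iterrows():
        t = traits[sp]
        density = row["abundance"] / study_area_km2
        out[sp] = density * t.home_range_km2 / t.group_size
    return out
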