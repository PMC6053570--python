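"""Sampling-site metadata for the Danish *Plantago major* survey.

Fifteen naturally occurring populations spread over three broad geographic
regions (western Jutland, eastern Jutland, the islands), four habitat types
and three qualitative light levels.  These assignments are study metadata:
region is a deterministic function of population, and habitat/light are
population-level attributes.
"""

from __future__ import annotations

import pandas as pd

WESTERN_JUTLAND = "western_jutland"
EASTERN_JUTLAND = "eastern_jutland"
ISLANDS = "islands"

REGIONS = (WESTERN_JUTLAND, EASTERN_JUTLAND, ISLANDS)
HABITATS = ("agricultural", "forest", "manicured_park", "meadow")
LIGHT_LEVELS = ("full_sun", "part_shade", "shade")
PHENOLOGY_STAGES = ("vegetative", "immature_flowers", "flowering")

# population, latitude, longitude, region, habitat, light
_SITE_ROWS = [
    ("Aalborg", 57.08, 9.91, EASTERN_JUTLAND, "meadow", "full_sun"),
    ("Falster", 54.80, 12.09, ISLANDS, "forest", "shade"),
    ("Grenaa", 56.41, 10.92, EASTERN_JUTLAND, "manicured_park", "full_sun"),
    ("Hannerupskov", 55.59, 9.72, EASTERN_JUTLAND, "forest", "shade"),
    ("Langeland", 54.92, 10.71, ISLANDS, "agricultural", "full_sun"),
    ("Nørre Nissum", 56.55, 8.42, WESTERN_JUTLAND, "agricultural", "full_sun"),
    ("Nyråd", 55.01, 11.96, ISLANDS, "forest", "part_shade"),
    ("Øjesø", 56.29, 10.61, EASTERN_JUTLAND, "forest", "part_shade"),
    ("Randers", 56.47, 10.02, EASTERN_JUTLAND, "manicured_park", "full_sun"),
    ("Ringkøbing", 56.10, 8.23, WESTERN_JUTLAND, "meadow", "full_sun"),
    ("Ringkøbing Ejstrup", 56.18, 8.28, WESTERN_JUTLAND, "agricultural", "full_sun"),
    ("Silkeborg", 56.23, 9.67, EASTERN_JUTLAND, "manicured_park", "full_sun"),
    ("Slæbæk", 55.11, 10.57, ISLANDS, "forest", "shade"),
    ("Slagelse", 55.43, 11.46, ISLANDS, "agricultural", "full_sun"),
    ("Vissenbjerg", 55.38, 10.13, ISLANDS, "meadow", "part_shade"),
]


def site_table() -> pd.DataFrame:
    """Return the default population table (one row per sampling site)."""
    return pd.DataFrame(
        _SITE_ROWS,
        columns=["population", "latitude", "longitude", "region", "habitat", "light"],
    )


REGION_OF_POPULATION = {row[0]: row[3] for row in _SITE_ROWS}
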