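"""Physical and reporting constants used throughout the pipeline.

These are echoed in every report header so a table can always be traced back
to the constants that produced it.
"""

from dataclasses import dataclass

#: Global ocean surface area used to scale mean areal concentration
#: (pieces km^-2) to a global particle count.
OCEAN_AREA_KM2: float = 361_900_000.0

#: Average mass of one floating plastic particle, grams. A single fixed
#: count-to-mass conversion; mass columns are exactly proportional to counts.
PARTICLE_MASS_G: float = 1.36e-2

#: Grams per million tonnes (1 tonne = 1e6 g).
GRAMS_PER_MILLION_TONNES: float = 1e12

#: Analysis window (inclusive) for the annual trend table.
FIRST_YEAR: int = 1979
LAST_YEAR: int = 2019


@dataclass(frozen=True)
class Constants:
    """Bundle of report constants, overridable for sensitivity runs."""

    ocean_area_km2: float = OCEAN_AREA_KM2
    particle_mass_g: float = PARTICLE_MASS_G
    first_year: int = FIRST_YEAR
    last_year: int = LAST_YEAR

    def as_dict(self) -> dict:
        return {
            "ocean_area_km2": self.ocean_area_km2,
            "particle_mass_g": self.particle_mass_g,
            "first_year": self.first_year,
            "last_year": self.last_year,
        }
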