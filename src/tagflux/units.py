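"""Radiolabel unit conversions.

Scintillation counts (dpm per 10^6 cells) are converted to carbon amounts
using the specific activity of the labeled substrate, and carbon amounts to
pool masses using fixed carbon-mass fractions: carbon is taken to be 40% of
the weight of starch and 80% of the weight of TAG.

All conversions are linear and are applied at full precision; rounding to
the one-decimal report precision happens only in the reporting layer
(:func:`round_half_away`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ConversionConstants",
    "CarbonAmount",
    "counts_to_carbon",
    "carbon_to_mass",
    "mass_to_carbon",
    "round_half_away",
]

#: Atomic mass of carbon, g/mol. The round value 12.0 is the one that
#: reproduces published starch masses at one-decimal precision
#: (1850 nmol C -> 55.5 µg; 12.011 would give 55.55 -> 55.6).
CARBON_ATOMIC_MASS = 12.0

#: Mass fraction of carbon in starch (C6H10O5 polymer, operational value).
CARBON_FRACTION_STARCH = 0.40

#: Mass fraction of carbon in triacylglycerol (operational value).
CARBON_FRACTION_TAG = 0.80


@dataclass(frozen=True)
class ConversionConstants:
    """Constants linking counts, carbon amounts and pool masses.

    Parameters
    ----------
    specific_activity
        Radioactivity per amount of labeled substrate, dpm per µmol
        bicarbonate (or per µmol palmitic acid for the acyl tracer).
    carbon_mass_fraction_starch, carbon_mass_fraction_tag
        Dimensionless carbon weight fractions used to turn nmol C into µg
        of polymer/lipid.
    carbon_atomic_mass
        g per mol of carbon.
    """

    specific_activity: float
    carbon_mass_fraction_starch: float = CARBON_FRACTION_STARCH
    carbon_mass_fraction_tag: float = CARBON_FRACTION_TAG
    carbon_atomic_mass: float = CARBON_ATOMIC_MASS

    def __post_init__(self) -> None:
        if not (math.isfinite(self.specific_activity) and self.specific_activity > 0):
            raise ValueError(
                f"specific_activity must be finite and > 0, got {self.specific_activity}"
            )
        for name in ("carbon_mass_fraction_starch", "carbon_mass_fraction_tag"):
            f = getattr(self, name)
            if not (0.0 < f <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {f}")
        if not self.carbon_atomic_mass > 0:
            raise ValueError("carbon_atomic_mass must be > 0")


@dataclass(frozen=True)
class CarbonAmount:
    """A labeled carbon amount, nmol C per 10^6 cells, tied to a pool."""

    value: float
    pool: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"carbon amount must be finite and >= 0, got {self.value}")


def counts_to_carbon(
    dpm: float, constants: ConversionConstants, pool: str = ""
) -> CarbonAmount:
    """Convert scintillation counts to a carbon amount.

    ``dpm / specific_activity`` gives µmol of labeled carbon, returned as
    nmol C per 10^6 cells (×1000). Assumes background-subtracted counts.
    """
    if not math.isfinite(dpm) or dpm < 0:
        raise ValueError(f"dpm must be finite and >= 0, got {dpm}")
    return CarbonAmount(value=1000.0 * dpm / constants.specific_activity, pool=pool)


def carbon_to_mass(
    carbon: CarbonAmount | float,
    fraction: float,
    atomic_mass: float = CARBON_ATOMIC_MASS,
) -> float:
    """Convert nmol C per 10^6 cells to µg of pool material per 10^6 cells.

    ``mass = carbon * atomic_mass * 1e-3 / fraction`` — nmol C × g/mol gives
    ng of carbon, scaled to µg, then divided by the carbon weight fraction
    of the pool (0.40 for starch, 0.80 for TAG).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"carbon mass fraction must be in (0, 1], got {fraction}")
    value = carbon.value if isinstance(carbon, CarbonAmount) else float(carbon)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"carbon amount must be finite and >= 0, got {value}")
    return value * atomic_mass * 1e-3 / fraction


def mass_to_carbon(
    mass: float,
    fraction: float,
    atomic_mass: float = CARBON_ATOMIC_MASS,
    pool: str = "",
) -> CarbonAmount:
    """Inverse of :func:`carbon_to_mass`: µg of pool material to nmol C."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"carbon mass fraction must be in (0, 1], got {fraction}")
    if not math.isfinite(mass) or mass < 0:
        raise ValueError(f"mass must be finite and >= 0, got {mass}")
    return CarbonAmount(value=mass * fraction * 1e3 / atomic_mass, pool=pool)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (report convention; 0.25 -> 0.3 at 1 dp).

    Python's built-in ``round`` is banker's rounding; report tables use the
    convention laboratory notebooks do.
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
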