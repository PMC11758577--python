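"""Beer-Lambert dye quantification.

Used to determine the TCPP porphyrin concentration from the absorbance of
its first Q-band at 520 nm (molar extinction coefficient
8900 M^-1 cm^-1, 0.1 cm path length in the study's cuvettes).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AbsorbanceMeasurement",
    "beer_lambert_concentration",
    "molarity_to_weight_percent",
    "quantify_csv",
    "TCPP_EPSILON_520",
    "TCPP_PATH_LENGTH_CM",
]

TCPP_EPSILON_520 = 8900.0   # M^-1 cm^-1 at 520 nm
TCPP_PATH_LENGTH_CM = 0.1


@dataclass(frozen=True)
class AbsorbanceMeasurement:
    absorbance: float
    wavelength: float = 520.0          # nm
    path_length: float = TCPP_PATH_LENGTH_CM   # cm
    molar_extinction: float = TCPP_EPSILON_520  # M^-1 cm^-1

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise ValueError("absorbance must be >= 0")
        if self.path_length <= 0:
            raise ValueError("path_length must be > 0")
        if self.molar_extinction <= 0:
            raise ValueError("molar_extinction must be > 0")


def beer_lambert_concentration(m: AbsorbanceMeasurement) -> float:
    """Molar concentration c = A / (epsilon * d)."""
    return m.absorbance / (m.molar_extinction * m.path_length)


def molarity_to_weight_percent(concentration_m: float, molar_mass: float,
                               dispersion_mg_per_ml: float) -> float:
    """Dye loading in wt% of the dispersed powder.

    The dye molar mass is an explicit input (g/mol), as is the powder
    dispersion concentration (mg/mL).
    """
    if molar_mass <= 0 or dispersion_mg_per_ml <= 0:
        raise ValueError("molar mass and dispersion must be > 0")
    # mol/L * g/mol = g/L, and g/L == mg/mL
    mg_per_ml_dye = concentration_m * molar_mass
    return 100.0 * mg_per_ml_dye / dispersion_mg_per_ml


def quantify_csv(path_in, path_out) -> pd.DataFrame:
    """Process a CSV with columns absorbance, molar_extinction, path_length
    into concentrations (mol/L)."""
    df = pd.read_csv(path_in)
    required = {"absorbance", "molar_extinction", "path_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path_in}: missing columns {sorted(missing)}")
    df["concentration_M"] = [
        beer_lambert_concentration(AbsorbanceMeasurement(
            absorbance=row.absorbance,
            molar_extinction=row.molar_extinction,
            path_length=row.path_length))
        for row in df.itertuples()
    ]
    df.to_csv(path_out, index=False)
    return df
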