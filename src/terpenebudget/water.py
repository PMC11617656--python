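"""Inner-bark solute and pressure potentials from osmometry.

Tissue solute potential follows the van 't Hoff relation applied to
vapor-pressure osmometry readings,

    psi_solute = -osmolality * R * T * 1e-6   (MPa),

with R = 8.3144598 J mol^-1 K^-1, osmolality in mmol kg^-1 and chamber
temperature in K (the 1e-6 collects the unit conversions, giving the
constant 0.0000083144598 MPa kg mmol^-1 K^-1).  The pressure (turgor)
potential is then estimated as

    psi_pressure = psi - psi_solute,

using the shoot predawn water potential as the inner-bark water potential —
an approximation inherited from the study design (no gradient correction is
applied).  Positive psi_pressure indicates turgid cells; negative values
indicate estimated turgor loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import Cohort

__all__ = [
    "VANT_HOFF_MPA_PER_MMOL_K",
    "DEFAULT_CHAMBER_TEMP_K",
    "WaterState",
    "solute_potential",
    "pressure_potential",
    "water_states",
]

#: MPa per (mmol kg^-1 . K): the gas constant scaled for these units.
VANT_HOFF_MPA_PER_MMOL_K = 8.3144598e-6

#: Default osmometer chamber temperature (K) when not measured.
DEFAULT_CHAMBER_TEMP_K = 305.0


@dataclass(frozen=True)
class WaterState:
    """Water-potential components of one tree's inner bark (MPa)."""

    tree_id: str
    psi_pd: float
    osmolality: float
    chamber_temp: float
    psi_solute: float
    psi_pressure: float


def solute_potential(osmolality: float, temp: float = DEFAULT_CHAMBER_TEMP_K):
    """Solute potential (MPa) from osmolality (mmol kg^-1) and temperature (K)."""
    osmolality = np.asarray(osmolality, dtype=float)
    if np.any(osmolality < 0):
        raise ValueError("osmolality must be >= 0 mmol kg^-1")
    if np.any(np.asarray(temp) <= 0):
        raise ValueError("temperature must be > 0 K")
    out = -osmolality * VANT_HOFF_MPA_PER_MMOL_K * temp
    return float(out) if out.ndim == 0 else out


def pressure_potential(psi_pd: float, psi_solute: float):
    """Estimated turgor: psi_pressure = psi - psi_solute (MPa)."""
    psi_solute = np.asarray(psi_solute, dtype=float)
    if np.any(psi_solute > 0):
        raise ValueError("psi_solute must be <= 0 MPa")
    out = np.asarray(psi_pd, dtype=float) - psi_solute
    return float(out) if out.ndim == 0 else out


def water_states(cohort: Cohort) -> pd.DataFrame:
    """Per-tree water-relations table for every tree with osmometry.

    Trees lacking a chamber temperature use the default 305.0 K.
    """
    rows = []
    for t in cohort:
        if t.osmolality is None:
            continue
        temp = t.chamber_temp if t.chamber_temp is not None else (
            DEFAULT_CHAMBER_TEMP_K
        )
        psi_s = solute_potential(t.osmolality, temp)
        rows.append(
            WaterState(
                tree_id=t.tree_id,
                psi_pd=t.psi_pd,
                osmolality=t.osmolality,
                chamber_temp=temp,
                psi_solute=psi_s,
                psi_pressure=pressure_potential(t.psi_pd, psi_s),
            ).__dict__
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tree_id", "psi_pd", "osmolality", "chamber_temp",
            "psi_solute", "psi_pressure",
        ],
    )
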