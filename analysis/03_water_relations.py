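#!/usr/bin/env python
"""Estimate inner-bark solute and pressure potentials.

psi_solute from osmometry (van 't Hoff at the chamber temperature),
psi_pressure = psi_pd - psi_solute; trees split into positive-turgor and
turgor-lost groups.  Writes results/water_state.csv.
"""

from pathlib import Path

from terpenebudget.datamodel import read_cohort
from terpenebudget.water import water_states

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "cohort" / "cohort.csv")
    tbl = water_states(cohort)
    tbl.to_csv(ROOT / "water_state.csv", index=False, float_format="%.10g")
    pos = (tbl["psi_pressure"] > 0).sum()
    print(f"psi_solute mean {tbl['psi_solute'].mean():.2f} MPa; "
          f"psi_pressure {tbl['psi_pressure'].min():.2f} .. "
          f"{tbl['psi_pressure'].max():.2f} MPa")
    print(f"{pos}/{len(tbl)} trees retain positive estimated turgor")
    print(f"wrote {ROOT / 'water_state.csv'}")


if __name__ == "__main__":
    main()
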