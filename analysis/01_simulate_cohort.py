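#!/usr/bin/env python
"""Generate the synthetic study cohort.

46 pinyon pines: 14 well-watered (psi_pd -0.31..-0.91 MPa), 16 mild drought
(-1.66..-2.85) and 16 moderate drought (-2.86..-3.61), with control /
girdled / inoculated / inoculated+girdled treatments balanced within each
stratum, and four desiccated trees whose post-inoculation tissue is
unavailable.  Writes cohort.csv, the 43-compound terpene matrices and the
noise-free truth table under results/cohort/.
"""

from pathlib import Path

from terpenebudget.datamodel import write_cohort
from terpenebudget.simulate import GeneratorParams, generate_cohort

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    params = GeneratorParams(seed=SEED)
    cohort = generate_cohort(params)
    paths = write_cohort(cohort, OUT)
    truth = cohort.provenance["truth"]
    truth.to_csv(OUT / "truth.csv", index=False, float_format="%.10g")

    n_watered = sum(t.water_group == "watered" for t in cohort)
    n_missing = sum(not t.has_post for t in cohort)
    print(f"cohort: {len(cohort)} trees "
          f"({n_watered} watered, {len(cohort) - n_watered} drought), "
          f"{n_missing} missing post-inoculation tissue")
    psis = sorted(t.psi_pd for t in cohort)
    print(f"psi_pd range: {psis[0]:.2f} .. {psis[-1]:.2f} MPa")
    print(f"wrote: {', '.join(Path(p).name for p in paths.values())}, truth.csv")


if __name__ == "__main__":
    main()
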