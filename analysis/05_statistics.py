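#!/usr/bin/env python
"""Fit the statistical layer and summarise the drought constraint.

Linear models (type-II ANOVA): induced MST vs psi_pd x inoculation, vs
drought x girdle, vs pre-inoculation NSC, vs estimated turgor; PERMANOVA on
Bray-Curtis dissimilarities of the post-inoculation terpene composition.
Writes results/models.json via the pipeline report.
"""

import json
from pathlib import Path

from terpenebudget.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    cfg = PipelineConfig(
        input_mode="file",
        cohort_path=str(ROOT / "cohort" / "cohort.csv"),
        terpenes_pre_path=str(ROOT / "cohort" / "terpenes_pre.csv"),
        terpenes_post_path=str(ROOT / "cohort" / "terpenes_post.csv"),
        n_perm=999,
        seed=SEED,
    )
    report = run_pipeline(cfg)
    report.write(ROOT / "report")

    m = report.models
    inter = [k for k in m["delta_vs_psi_by_inoculation"]["anova_type2"]
             if ":" in k]
    p_inter = m["delta_vs_psi_by_inoculation"]["anova_type2"][inter[0]]["PR(>F)"]
    print(f"psi_pd x inoculation interaction: p = {p_inter:.2g}")
    print(f"induction ~ psi_pd slope (I cell): "
          f"{report.headline['induction_slope_per_mpa']['estimate']:.1f} "
          f"+/- {report.headline['induction_slope_per_mpa']['se']:.1f} "
          f"mg g^-1 MPa^-1")
    print(f"induction ~ pre-inoculation NSC: p = "
          f"{m['induction_vs_nsc']['anova_type2']['nsc_pre_total']['PR(>F)']:.2f}"
          f" (R^2 = {m['induction_vs_nsc']['r_squared']:.2f})")
    print(f"induction ~ psi_pressure: R^2 = "
          f"{m['induction_vs_pressure']['r_squared']:.2f}, p = "
          f"{m['induction_vs_pressure']['anova_type2']['psi_pressure']['PR(>F)']:.2g}")
    perm = m["permanova_post_composition"]["table"]
    print("PERMANOVA (post composition): "
          + ", ".join(f"{t} p={perm[t]['p_value']:.3f}"
                      for t in perm if t != "Residual"))
    ratio = report.headline["induction_by_pressure_group"]["ratio"]
    print(f"induction ratio, positive vs lost turgor: {ratio:.1f}x")
    print(f"wrote {ROOT / 'report'}/(models.json, report.json, *.csv)")


if __name__ == "__main__":
    main()
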