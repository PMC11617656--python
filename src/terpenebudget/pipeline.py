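"""End-to-end orchestration: cohort -> girdle correction -> water relations
-> stoichiometric budget -> statistics -> report.

A :class:`PipelineConfig` fully determines a run: input mode (synthetic
generator or CSV files), the correction convention, energy conventions,
maintenance mode, permutation count and seeds.  The report echoes every
scalar back (the analysis hinges on auditable constants: the maintenance
percentage, the glucose cost, the clip bounds) and identical config + seeds
reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import girdle, stats, stoichiometry, water
from .datamodel import Cohort, read_cohort, write_results
from .simulate import GeneratorParams, generate_cohort

__all__ = ["PipelineConfig", "Report", "PipelineStageError", "run_pipeline",
           "headline_summary"]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and offending context."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    input_mode: str = "synthetic"              # "synthetic" | "file"
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    cohort_path: str | None = None
    terpenes_pre_path: str | None = None
    terpenes_post_path: str | None = None
    convention: str = "printed"                # girdle-correction convention
    energy: stoichiometry.EnergyConventions = field(
        default_factory=stoichiometry.EnergyConventions
    )
    maintenance: str | float = "auto"          # "auto" -> girdled-tree mean
    nsc_pool: str = "total_nsc"
    n_perm: int = 999
    seed: int = 0
    compound_class: str = "monoterpene"
    pathway: str = "MEP"
    with_profiles: bool = True  # skip terpene matrices (and PERMANOVA) if False

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "file"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.input_mode == "file" and self.cohort_path is None:
            raise ValueError("file mode requires cohort_path")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        js = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(js.encode()).hexdigest()[:16]


@dataclass
class Report:
    """Tables, model summaries and headline quantities of one run."""

    tables: dict[str, pd.DataFrame]
    models: dict
    headline: dict
    provenance: dict

    def write(self, out_dir: str | Path) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = write_results(self.tables, self.models, out)
        report = {
            "headline": self.headline,
            "provenance": self.provenance,
            "models": self.models,
        }
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_jsonify) + "\n"
        )
        return manifest


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _load_cohort(config: PipelineConfig) -> Cohort:
    if config.input_mode == "synthetic":
        params = dataclasses.replace(config.generator, seed=config.seed)
        return generate_cohort(params, with_profiles=config.with_profiles)
    for name, p in (
        ("cohort", config.cohort_path),
        ("terpenes_pre", config.terpenes_pre_path),
        ("terpenes_post", config.terpenes_post_path),
    ):
        if p is None or not Path(p).exists():
            raise PipelineStageError(
                f"stage=input: required file for {name!r} missing: {p}"
            )
    return read_cohort(
        config.cohort_path,
        terpenes_pre=config.terpenes_pre_path,
        terpenes_post=config.terpenes_post_path,
    )


def run_pipeline(config: PipelineConfig) -> Report:
    """Execute all stages; see the module docstring for the stage order."""
    cohort = _load_cohort(config)
    exclusions: list[dict] = []

    # --- girdle correction -------------------------------------------------
    try:
        loss_model = girdle.fit_loss_model(cohort)
        changes = girdle.correct_cohort(cohort, loss_model, config.convention)
    except Exception as e:  # noqa: BLE001 - annotate stage and re-raise
        raise PipelineStageError(f"stage=girdle_correction: {e}") from e
    by_id = {t.tree_id: t for t in cohort}
    for t in cohort:
        if not t.has_post:
            exclusions.append(
                {"tree_id": t.tree_id, "stage": "girdle_correction",
                 "reason": "missing post-inoculation tissue"}
            )
    induction = pd.DataFrame(
        [
            {
                "tree_id": c.tree_id,
                "treatment": by_id[c.tree_id].treatment,
                "water_group": by_id[c.tree_id].water_group,
                "girdled": by_id[c.tree_id].girdled,
                "inoculated": by_id[c.tree_id].inoculated,
                "psi_pd": by_id[c.tree_id].psi_pd,
                "mst_pre": by_id[c.tree_id].mst_pre,
                "mst_post": by_id[c.tree_id].mst_post,
                "delta_t_raw": c.delta_t_raw,
                "correction": c.correction,
                "delta_t_corrected": c.delta_t_corrected,
                "convention": c.convention,
            }
            for c in changes
        ]
    )

    # --- water relations ---------------------------------------------------
    try:
        water_tbl = water.water_states(cohort)
    except Exception as e:
        raise PipelineStageError(f"stage=water_relations: {e}") from e

    # --- stoichiometric budget ---------------------------------------------
    try:
        ledger = stoichiometry.glucose_cost(
            config.compound_class, config.pathway, config.energy
        )
        if config.maintenance == "auto":
            maint = stoichiometry.maintenance_fraction(cohort, config.nsc_pool)
        else:
            maint = float(config.maintenance)
        corrected = induction.set_index("tree_id")["delta_t_corrected"]
        budgets = []
        for t in cohort:
            if not (t.girdled and t.inoculated):
                continue
            if not t.has_post:
                continue
            b = stoichiometry.budget_for_tree(
                t, ledger.mass_cost, maint, float(corrected[t.tree_id]),
                pool=config.nsc_pool,
            )
            if b.excluded:
                exclusions.append(
                    {"tree_id": t.tree_id, "stage": "stoichiometry",
                     "reason": "no induction observed (delta <= 0)"}
                )
            budgets.append(b)
    except Exception as e:
        raise PipelineStageError(f"stage=stoichiometry: {e}") from e
    stoich_tbl = pd.DataFrame(
        [
            {
                "tree_id": b.tree_id,
                "nsc_pre_pct_dw": b.nsc_pre,
                "maintenance_pct": b.maintenance,
                "nsc_available_pct_dw": b.nsc_avail,
                "glucose_cost_g_per_g": b.glucose_cost,
                "max_potential_mst_mg_per_g": b.max_potential_mst,
                "observed_delta_t_mg_per_g": b.observed_delta_t,
                "potential_percent_induction": (
                    np.nan if b.excluded else b.potential_percent
                ),
                "excluded_no_induction": b.excluded,
            }
            for b in budgets
        ]
    )

    # --- statistics ----------------------------------------------------------
    models: dict = {
        "loss_model": {
            "intercept": loss_model.intercept,
            "slope_per_mpa": loss_model.slope,
            "n": loss_model.n,
            "r_squared": loss_model.r_squared,
            "residual_sd": loss_model.residual_sd,
            "se_intercept": loss_model.se_intercept,
            "se_slope": loss_model.se_slope,
        },
        "cost_ledger": ledger.as_dict(),
        "maintenance_pct": maint,
        "correction_convention": config.convention,
    }
    try:
        frame = induction.merge(
            water_tbl[["tree_id", "psi_solute", "psi_pressure"]],
            on="tree_id", how="left",
        )
        frame["drought"] = np.where(frame["water_group"] == "drought",
                                    "drought", "watered")
        frame["nsc_pre_total"] = [
            by_id[i].nsc_pre.total_nsc for i in frame["tree_id"]
        ]

        lm_psi = stats.fit_lm(
            frame, "delta_t_corrected ~ psi_pd * inoculated"
        )
        models["delta_vs_psi_by_inoculation"] = lm_psi.summary_dict()

        inoc = frame[frame["inoculated"]].copy()
        lm_dg = stats.fit_lm(inoc, "delta_t_corrected ~ drought * girdled")
        models["induction_vs_drought_by_girdle"] = lm_dg.summary_dict()

        lm_nsc = stats.fit_lm(inoc, "delta_t_corrected ~ nsc_pre_total")
        models["induction_vs_nsc"] = lm_nsc.summary_dict()

        inoc_p = inoc.dropna(subset=["psi_pressure"])
        lm_press = stats.fit_lm(inoc_p, "delta_t_corrected ~ psi_pressure")
        models["induction_vs_pressure"] = lm_press.summary_dict()

        # slope estimated on nongirdled inoculated trees: girdling scales the
        # post pool multiplicatively, so the I cell carries the clean signal
        inoc_ng = inoc[~inoc["girdled"]]
        lm_slope = stats.fit_lm(inoc_ng, "delta_t_corrected ~ psi_pd")
        models["induction_vs_psi_inoculated"] = lm_slope.summary_dict()

        if cohort.terpenes_post is not None and len(cohort.terpenes_post) >= 8:
            post = cohort.terpenes_post
            design = pd.DataFrame(
                {
                    "drought": [by_id[i].water_group for i in post.index],
                    "inoculated": [by_id[i].inoculated for i in post.index],
                },
                index=[str(i) for i in post.index],
            )
            dm = stats.bray_curtis(post, relative=True)
            perm = stats.permanova(
                dm, design, n_perm=config.n_perm, seed=config.seed + 1000
            )
            models["permanova_post_composition"] = {
                "n_permutations": perm.n_permutations,
                "seed": perm.seed,
                "table": {
                    term: {k: (None if pd.isna(v) else float(v))
                           for k, v in row.items()}
                    for term, row in perm.table.to_dict("index").items()
                },
            }
    except Exception as e:
        raise PipelineStageError(f"stage=statistics: {e}") from e

    tables = {
        "induction": induction,
        "stoichiometry": stoich_tbl,
        "water_state": water_tbl,
        "exclusions": pd.DataFrame(
            exclusions, columns=["tree_id", "stage", "reason"]
        ),
    }
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_trees": len(cohort),
    }
    report = Report(tables=tables, models=models,
                    headline={}, provenance=provenance)
    report.headline = headline_summary(report)
    return report


def headline_summary(report: Report) -> dict:
    """Key quantities of a completed run, each traceable to a report table.

    * mean girdle-corrected induction by water group (inoculated trees);
    * mean +/- SE of the potential percent induction for watered
      inoculated+girdled trees that induced;
    * mean induction in the psi_pressure > 0 vs <= 0 groups and their ratio;
    * R^2 of induction ~ psi_pressure and the induction ~ psi_pd slope among
      inoculated trees.

    Empty cells are reported as ``None`` (unavailable), never fabricated.
    """
    ind = report.tables["induction"]
    stoich = report.tables["stoichiometry"]
    wat = report.tables["water_state"]
    out: dict = {}

    inoc = ind[ind["inoculated"]]
    out["mean_induction_by_water_group"] = {
        g: (float(v.mean()) if len(v) else None)
        for g, v in inoc.groupby("water_group")["delta_t_corrected"]
    }

    watered_ids = set(ind[ind["water_group"] == "watered"]["tree_id"])
    w = stoich[
        stoich["tree_id"].isin(watered_ids) & ~stoich["excluded_no_induction"]
    ]["potential_percent_induction"].dropna()
    if len(w):
        out["potential_percent_watered_ig"] = {
            "mean": float(w.mean()),
            "se": float(w.std(ddof=1) / np.sqrt(len(w))) if len(w) > 1 else None,
            "n": int(len(w)),
        }
    else:
        out["potential_percent_watered_ig"] = None

    merged = inoc.merge(wat[["tree_id", "psi_pressure"]], on="tree_id",
                        how="inner").dropna(subset=["psi_pressure"])
    pos = merged[merged["psi_pressure"] > 0]["delta_t_corrected"]
    neg = merged[merged["psi_pressure"] <= 0]["delta_t_corrected"]
    mean_pos = float(pos.mean()) if len(pos) else None
    mean_neg = float(neg.mean()) if len(neg) else None
    out["induction_by_pressure_group"] = {
        "positive_turgor_mean": mean_pos,
        "negative_turgor_mean": mean_neg,
        "ratio": (
            mean_pos / mean_neg
            if mean_pos is not None and mean_neg not in (None, 0.0)
            else None
        ),
        "n_positive": int(len(pos)),
        "n_negative": int(len(neg)),
    }

    m = report.models
    out["r2_induction_vs_pressure"] = (
        m["induction_vs_pressure"]["r_squared"]
        if "induction_vs_pressure" in m else None
    )
    if "induction_vs_psi_inoculated" in m:
        out["induction_slope_per_mpa"] = {
            "estimate": m["induction_vs_psi_inoculated"]["coefficients"]["psi_pd"],
            "se": m["induction_vs_psi_inoculated"]["std_errors"]["psi_pd"],
        }
    out["girdle_loss_line"] = m["loss_model"]
    out["glucose_cost_g_per_g"] = m["cost_ledger"]["mass_cost_g_per_g"]
    out["maintenance_pct"] = m["maintenance_pct"]
    return out
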