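"""Synthetic experimental cohorts with the structure of the glasshouse study.

The generator emulates a 46-tree pinyon pine drought x girdle x inoculation
experiment: 14 watered trees plus 32 droughted trees split into mild and
moderate strata by predawn water potential, four treatment cells (control,
girdled, inoculated, inoculated+girdled) allocated evenly within each
stratum, fungal-induced terpene accumulation that declines linearly with
psi_pd, girdle-induced resin loss that is worse in watered trees,
treatment-dependent NSC depletion, osmotic-adjustment-driven osmolality, and
a 43-compound terpene composition whose induced shift is expressed only in
watered inoculated trees.

Every default is either a study condition (sample sizes, psi ranges, effect
sizes, depletion means) or a realistic choice documented in the methods
note.  The generator reproduces statistical structure only; it does not
simulate resin-duct pressure dynamics or phloem transport.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import Cohort, NSCProfile, TreeRecord

__all__ = ["GeneratorParams", "generate_cohort", "truth_table", "loss_line"]

TREATMENTS = ("C", "G", "I", "I+G")


class ParameterError(ValueError):
    """Generator parameters are infeasible."""


@dataclass(frozen=True)
class GeneratorParams:
    """Configurable study conditions for :func:`generate_cohort`.

    Stratum sizes, psi_pd ranges, the induction slope and the watered-group
    induction mean, NSC pools and depletion fractions, the girdle-loss
    anchors and the chamber temperature are the experiment's conditions;
    noise scales, the constitutive terpene pool and the compositional
    parameters are generator choices (see the methods note).
    """

    # cohort structure
    n_watered: int = 14
    n_mild: int = 16
    n_moderate: int = 16
    psi_range_watered: tuple[float, float] = (-0.91, -0.31)
    psi_range_mild: tuple[float, float] = (-2.85, -1.66)
    psi_range_moderate: tuple[float, float] = (-3.61, -2.86)

    # induced terpene response (mg g^-1 DW)
    induction_slope: float = 15.9          # per MPa; less negative psi -> more
    watered_induction_mean: float = 49.3   # at the watered-stratum mean psi
    constrained_induction_mean: float = 11.9  # reference mean, turgor-lost trees
    constitutive_mst_mean: float = 30.0
    constitutive_mst_sd: float = 8.0
    mst_noise_sd: float = 10.0             # additive, nongirdled trees
    girdle_rel_noise_sd: float = 0.05      # relative, girdled trees

    # girdle-induced resin loss: two (psi, relative loss) anchors define a line
    girdle_loss_anchors: tuple[tuple[float, float], tuple[float, float]] = (
        (-0.31, -0.43),
        (-3.61, 0.0),
    )

    # NSC pools (% DW)
    sugar_pre_mean: float = 5.4
    sugar_pre_sd: float = 1.4
    starch_pre_watered: tuple[float, float] = (0.3, 0.1)   # mean, sd
    starch_pre_drought: tuple[float, float] = (0.03, 0.03)
    # relative NSC depletion over the inoculation period, percent (mean, sd)
    depletion_pct: dict = field(
        default_factory=lambda: {
            "C": (0.0, 8.0),
            "G": (52.0, 11.0),
            "I": (76.0, 10.0),
            "I+G": (89.0, 10.0),
        }
    )

    # inner-bark osmometry
    osmolality_base: float = 800.0      # mmol kg^-1 at psi_pd = 0
    osmolality_per_mpa: float = 100.0   # osmotic adjustment per MPa of stress
    osmolality_sd: float = 60.0
    chamber_temp_mean: float = 305.0    # K
    chamber_temp_sd: float = 0.2

    # terpene composition
    n_compounds: int = 43
    composition_shift: float = 1.0      # induced-vs-constitutive mean log-shift
    composition_concentration: float = 150.0  # Dirichlet concentration

    # missing post-inoculation tissue (desiccated trees)
    n_missing_post: int = 4

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_watered, self.n_mild, self.n_moderate) < 0:
            raise ParameterError("stratum counts must be >= 0")
        for lo, hi in (self.psi_range_watered, self.psi_range_mild,
                       self.psi_range_moderate):
            if not (-4.0 <= lo <= hi <= 0.0):
                raise ParameterError(f"psi range ({lo}, {hi}) outside [-4, 0]")
        for sd in (self.constitutive_mst_sd, self.mst_noise_sd,
                   self.girdle_rel_noise_sd, self.sugar_pre_sd,
                   self.osmolality_sd, self.chamber_temp_sd):
            if sd < 0:
                raise ParameterError("noise sd's must be >= 0")
        if self.n_missing_post < 0:
            raise ParameterError("n_missing_post must be >= 0")
        if self.n_compounds < 1:
            raise ParameterError("n_compounds must be >= 1")

    # -- derived structure -------------------------------------------------

    @property
    def n_total(self) -> int:
        return self.n_watered + self.n_mild + self.n_moderate

    @property
    def psi_anchor(self) -> float:
        """psi_pd at which the induction line equals the watered mean."""
        lo, hi = self.psi_range_watered
        return 0.5 * (lo + hi)

    def induction_at(self, psi_pd: float) -> float:
        """Expected induced terpene increment (before girdle loss), mg g^-1."""
        return self.watered_induction_mean + self.induction_slope * (
            psi_pd - self.psi_anchor
        )

    def scaled_to(self, n_total: int) -> "GeneratorParams":
        """Same conditions with stratum counts rescaled to ``n_total`` trees
        (largest-remainder rounding, missing-post count rescaled likewise)."""
        counts = np.array([self.n_watered, self.n_mild, self.n_moderate], float)
        quota = counts / counts.sum() * n_total
        alloc = np.floor(quota).astype(int)
        rem = n_total - alloc.sum()
        order = np.argsort(-(quota - alloc))
        alloc[order[:rem]] += 1
        n_miss = int(round(self.n_missing_post / counts.sum() * n_total))
        return dataclasses.replace(
            self, n_watered=int(alloc[0]), n_mild=int(alloc[1]),
            n_moderate=int(alloc[2]), n_missing_post=n_miss,
        )


def loss_line(params: GeneratorParams):
    """Relative girdle-loss line through the two anchors, clipped to [-1, 0].

    Returns ``f(psi) -> relative loss`` together with its (intercept, slope);
    more loss (more negative) at less negative psi_pd.
    """
    (p0, l0), (p1, l1) = params.girdle_loss_anchors
    if p0 == p1:
        raise ParameterError("girdle-loss anchors need distinct psi values")
    slope = (l0 - l1) / (p0 - p1)
    intercept = l0 - slope * p0

    def f(psi):
        return np.clip(intercept + slope * np.asarray(psi, float), -1.0, 0.0)

    f.intercept = intercept
    f.slope = slope              # per MPa of psi_pd
    f.stress_slope = -slope      # per MPa of drought stress (-psi_pd)
    return f


def _compound_names(n: int) -> list[str]:
    return [f"cmpd_{i:02d}" for i in range(1, n + 1)]


def _composition_means(params: GeneratorParams, rng: np.random.Generator):
    """Constitutive and induced mean composition vectors (each sums to 1).

    The induced blend tilts the constitutive one along a fixed +/-1 pattern
    in log space; ``composition_shift`` = 0 makes them identical.
    """
    w = rng.gamma(shape=2.0, scale=1.0, size=params.n_compounds) + 0.05
    constitutive = w / w.sum()
    pattern = np.where(np.arange(params.n_compounds) % 2 == 0, 1.0, -1.0)
    induced = constitutive * np.exp(params.composition_shift * pattern)
    induced = induced / induced.sum()
    return constitutive, induced


def generate_cohort(
    params: GeneratorParams | None = None,
    with_profiles: bool = True,
) -> Cohort:
    """Draw one synthetic cohort.

    Structure: psi_pd uniform within each stratum's range; treatments cycled
    through a shuffled order within stratum (cells of 3-4 trees at the
    default sizes); inoculated trees gain an induction increment linear in
    psi_pd; girdled trees lose a relative fraction of their post-MST given by
    the loss line (with relative noise); NSC pools deplete by treatment;
    osmolality rises with drought stress so that estimated pressure potential
    is positive for most watered trees and negative for most moderate-drought
    trees.  ``with_profiles=False`` skips the per-compound terpene matrices
    (cheaper for large parameter-recovery simulations).
    """
    if params is None:
        params = GeneratorParams()
    rng = np.random.default_rng(params.seed)
    loss = loss_line(params)
    names = _compound_names(params.n_compounds)
    m_const, m_induced = _composition_means(params, rng)

    strata = (
        ("well_watered", "watered", params.n_watered, params.psi_range_watered),
        ("mild", "drought", params.n_mild, params.psi_range_mild),
        ("moderate", "drought", params.n_moderate, params.psi_range_moderate),
    )

    trees: list[TreeRecord] = []
    truth_rows: list[dict] = []
    pre_profiles: dict[str, np.ndarray] = {}
    post_profiles: dict[str, np.ndarray] = {}
    idx = 0
    for stratum, group, n, (lo, hi) in strata:
        order = rng.permutation(
            [TREATMENTS[i % 4] for i in range(n)]
        )
        psis = rng.uniform(lo, hi, size=n) if n else np.array([])
        for j in range(n):
            idx += 1
            tree_id = f"T{idx:03d}"
            treatment = order[j]
            girdled = "G" in treatment
            inoculated = "I" in treatment
            psi = float(psis[j])

            mst_pre = max(
                1.0,
                params.constitutive_mst_mean
                + params.constitutive_mst_sd * rng.standard_normal(),
            )
            induction = params.induction_at(psi) if inoculated else 0.0
            true_loss = float(loss(psi)) if girdled else 0.0
            if girdled:
                rel = true_loss + params.girdle_rel_noise_sd * rng.standard_normal()
                mst_post = max(0.0, (mst_pre + induction) * (1.0 + rel))
            else:
                mst_post = max(
                    0.0,
                    mst_pre + induction
                    + params.mst_noise_sd * rng.standard_normal(),
                )

            sugar = max(0.2, params.sugar_pre_mean
                        + params.sugar_pre_sd * rng.standard_normal())
            st_mean, st_sd = (
                params.starch_pre_watered if group == "watered"
                else params.starch_pre_drought
            )
            starch = max(0.0, st_mean + st_sd * rng.standard_normal())
            # soluble pool split: sucrose-dominated, jittered
            frac = np.array([0.5, 0.25, 0.25])
            frac = frac + 0.03 * rng.standard_normal(3)
            frac = np.clip(frac, 0.05, None)
            frac = frac / frac.sum()
            nsc_pre = NSCProfile(
                starch=starch,
                sucrose=sugar * frac[0],
                glucose=sugar * frac[1],
                fructose=sugar * frac[2],
            )
            dep_mean, dep_sd = params.depletion_pct[treatment]
            dep = min(100.0, dep_mean + dep_sd * rng.standard_normal())
            retain = 1.0 - dep / 100.0
            nsc_post = NSCProfile(
                starch=max(0.0, nsc_pre.starch * retain),
                sucrose=max(0.0, nsc_pre.sucrose * retain),
                glucose=max(0.0, nsc_pre.glucose * retain),
                fructose=max(0.0, nsc_pre.fructose * retain),
            )

            osmolality = max(
                0.0,
                params.osmolality_base
                + params.osmolality_per_mpa * (-psi)
                + params.osmolality_sd * rng.standard_normal(),
            )
            temp = params.chamber_temp_mean + params.chamber_temp_sd * (
                rng.standard_normal()
            )

            trees.append(
                TreeRecord(
                    tree_id=tree_id,
                    water_group=group,
                    drought_stratum=stratum,
                    girdled=girdled,
                    inoculated=inoculated,
                    psi_pd=psi,
                    osmolality=osmolality,
                    chamber_temp=temp,
                    mst_pre=mst_pre,
                    mst_post=mst_post,
                    nsc_pre=nsc_pre,
                    nsc_post=nsc_post,
                )
            )
            truth_rows.append(
                {
                    "tree_id": tree_id,
                    "drought_stratum": stratum,
                    "treatment": treatment,
                    "psi_pd": psi,
                    "e_induction": induction,
                    "e_induction_at_stratum_mean_psi": (
                        params.induction_at(0.5 * (lo + hi)) if inoculated else 0.0
                    ),
                    "true_girdle_loss": true_loss,
                    "e_delta_observed": (mst_pre + induction) * (1.0 + true_loss)
                    - mst_pre,
                    "e_depletion_pct": dep_mean,
                    "e_nsc_post_total": nsc_pre.total_nsc * (1.0 - dep_mean / 100.0),
                }
            )

            if with_profiles:
                alpha_c = params.composition_concentration * m_const
                pre_profiles[tree_id] = mst_pre * rng.dirichlet(alpha_c)
                induced_blend = inoculated and group == "watered"
                alpha_p = params.composition_concentration * (
                    m_induced if induced_blend else m_const
                )
                post_profiles[tree_id] = mst_post * rng.dirichlet(alpha_p)

    # desiccated trees: post tissue unavailable; prefer the driest stratum
    if params.n_missing_post:
        drought_ids = [t.tree_id for t in trees
                       if t.drought_stratum == "moderate"] or [
            t.tree_id for t in trees
        ]
        k = min(params.n_missing_post, len(drought_ids))
        missing = set(rng.choice(drought_ids, size=k, replace=False))
        trees = [
            dataclasses.replace(t, mst_post=None, nsc_post=None)
            if t.tree_id in missing
            else t
            for t in trees
        ]
        for tid in missing:
            post_profiles.pop(tid, None)

    cohort = Cohort(
        trees,
        terpenes_pre=(
            pd.DataFrame.from_dict(pre_profiles, orient="index", columns=names)
            .rename_axis("tree_id")
            if with_profiles
            else None
        ),
        terpenes_post=(
            pd.DataFrame.from_dict(post_profiles, orient="index", columns=names)
            .rename_axis("tree_id")
            if with_profiles
            else None
        ),
        provenance={
            "generator": "terpenebudget.simulate.generate_cohort",
            "seed": params.seed,
            "params": dataclasses.asdict(params),
        },
    )
    cohort.provenance["truth"] = pd.DataFrame(truth_rows)
    return cohort


def truth_table(params: GeneratorParams | None = None) -> pd.DataFrame:
    """Noise-free per-tree expectations for the cohort ``params`` generates.

    Columns include the expected induction increment at the tree's realised
    psi_pd and at its stratum's mean psi, the true (clipped) girdle-loss
    fraction, the expected observed delta-MST given the realised
    pre-inoculation pool, and the expected post NSC total under the
    treatment-mean depletion.  Reproduces the same draws as
    :func:`generate_cohort` for the same params/seed.
    """
    if params is None:
        params = GeneratorParams()
    return generate_cohort(params, with_profiles=False).provenance["truth"]
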