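"""Stoichiometric cost of terpene synthesis and the de novo induction budget.

The question the budget answers: could the nonstructural carbohydrates (NSC)
present in the isolated inner bark at inoculation have paid for the terpene
induction actually observed?  The account has three steps:

1. ``glucose_cost`` builds an itemized ledger of what one mole of mono- or
   sesquiterpene costs in glucose: carbon skeleton (one glucose per C5
   isoprenoid unit via the plastidic MEP route: pyruvate + glyceraldehyde
   3-phosphate condense to DXP with loss of one CO2), plus the pathway's
   ATP, CTP and reductant demands, minus glycolytic co-product credits, with
   net ATP and NADPH converted to glucose equivalents under explicit
   respiratory conventions.  Under the defaults the cost is ~3.34 g glucose
   per g terpene, identical for the C10 and C15 classes (both are (C5H8)n).
2. ``nsc_available`` discounts the pre-inoculation NSC pool by the fraction
   consumed by baseline maintenance metabolism, estimated as the mean
   relative NSC drawdown of girdled-but-noninoculated trees
   (``maintenance_fraction``).
3. ``max_potential_mst`` converts what remains into the largest terpene
   increment it could synthesize, and ``potential_percent_induction``
   expresses that as a percentage of the induction observed.  Trees with no
   observed induction (post <= pre) are excluded, never divided by.

The budget is defined for inoculated+girdled trees only: girdling isolates
the stem segment so that only local NSC can have fuelled synthesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import Cohort, TreeRecord, pct_dw_to_mg_per_g

__all__ = [
    "M_GLUCOSE",
    "MOLAR_MASS",
    "IPP_PER_MOLECULE",
    "EnergyConventions",
    "CostLedger",
    "DeNovoBudget",
    "glucose_cost",
    "maintenance_fraction",
    "nsc_available",
    "max_potential_mst",
    "potential_percent_induction",
    "budget_for_tree",
]

M_GLUCOSE = 180.156  # g mol^-1, C6H12O6

#: Molar masses of the pure hydrocarbon classes (g mol^-1).
MOLAR_MASS = {"monoterpene": 136.234, "sesquiterpene": 204.351}  # C10H16, C15H24

#: C5 isoprenoid (IPP/DMAPP) units per terpene molecule.
IPP_PER_MOLECULE = {"monoterpene": 2, "sesquiterpene": 3}


class ScopeError(ValueError):
    """The budget was requested for a tree it is not defined for."""


@dataclass(frozen=True)
class EnergyConventions:
    """Respiratory conventions converting cofactor demands to glucose.

    atp_per_glucose
        mol ATP yielded per mol glucose fully respired (default 32).
    nadph_per_glucose_opp
        mol NADPH per mol glucose oxidised through the oxidative
        pentose-phosphate route (default 12).
    po_ratio_nadh
        ATP credited per NADH reoxidised in the mitochondrion (default 2.5).
    ctp_atp_equiv
        ATP equivalents per CTP regenerated (default 2).
    reductant_per_2e_step
        NADPH equivalents per two-electron reduction step (default 1).
    """

    atp_per_glucose: float = 32.0
    nadph_per_glucose_opp: float = 12.0
    po_ratio_nadh: float = 2.5
    ctp_atp_equiv: float = 2.0
    reductant_per_2e_step: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "atp_per_glucose",
            "nadph_per_glucose_opp",
            "po_ratio_nadh",
            "ctp_atp_equiv",
            "reductant_per_2e_step",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"energy convention {name} must be > 0")


@dataclass(frozen=True)
class CostLedger:
    """Itemized per-mole account of terpene synthesis cost.

    All line items are mol per mol terpene.  ``glucose_equivalents_total``
    and ``mass_cost`` are derived; the full ledger is always reported so
    every ATP/NADPH line is auditable.
    """

    compound_class: str
    pathway: str
    n_ipp: int
    skeleton_glucose: float       # glucose consumed for the carbon skeleton
    atp_demand: float             # pathway kinase ATP + glycolytic investment
    ctp_demand: float
    nadph_demand: float
    atp_credit: float             # substrate-level ATP from glycolysis
    nadh_credit: float            # glycolytic (+PDH for MVA) NADH
    conventions: EnergyConventions = field(default_factory=EnergyConventions)

    @property
    def net_atp_equiv(self) -> float:
        """Net ATP demand after CTP conversion and NADH/ATP credits
        (negative = net energy surplus from skeleton formation)."""
        c = self.conventions
        return (
            self.atp_demand
            + self.ctp_demand * c.ctp_atp_equiv
            - self.atp_credit
            - self.nadh_credit * c.po_ratio_nadh
        )

    @property
    def glucose_for_atp(self) -> float:
        return self.net_atp_equiv / self.conventions.atp_per_glucose

    @property
    def glucose_for_nadph(self) -> float:
        return self.nadph_demand / self.conventions.nadph_per_glucose_opp

    @property
    def glucose_equivalents_total(self) -> float:
        """Mol glucose per mol terpene."""
        return self.skeleton_glucose + self.glucose_for_nadph + self.glucose_for_atp

    @property
    def molar_mass(self) -> float:
        return MOLAR_MASS[self.compound_class]

    @property
    def mass_cost(self) -> float:
        """Grams glucose per gram terpene."""
        return self.glucose_equivalents_total * M_GLUCOSE / self.molar_mass

    def as_dict(self) -> dict:
        return {
            "compound_class": self.compound_class,
            "pathway": self.pathway,
            "n_ipp": self.n_ipp,
            "skeleton_glucose_mol": self.skeleton_glucose,
            "atp_demand_mol": self.atp_demand,
            "ctp_demand_mol": self.ctp_demand,
            "nadph_demand_mol": self.nadph_demand,
            "atp_credit_mol": self.atp_credit,
            "nadh_credit_mol": self.nadh_credit,
            "net_atp_equiv_mol": self.net_atp_equiv,
            "glucose_for_atp_mol": self.glucose_for_atp,
            "glucose_for_nadph_mol": self.glucose_for_nadph,
            "glucose_equivalents_total_mol": self.glucose_equivalents_total,
            "molar_mass_g_mol": self.molar_mass,
            "mass_cost_g_per_g": self.mass_cost,
        }


# Per-IPP stoichiometry.
#
# MEP (plastidic): glucose --glycolysis--> pyruvate + GA3P (2 ATP invested,
# 2 ATP and 1 NADH returned); DXS condenses them to DXP releasing CO2; then
# DXR (NADPH), CTP activation (IspD), one kinase ATP (IspE), and the IspG and
# IspH reductions (one 2e- step each) give IPP.  Totals per IPP: 1 glucose
# skeleton, 3 two-electron reductions, 1 ATP + 1 CTP, credits 1 NADH + net-0
# glycolytic ATP (2 invested, 2 returned).
#
# MVA (cytosolic): 3 acetyl-CoA per IPP require 1.5 glucose (glycolysis:
# 3 ATP invested, 6 returned, 3 NADH; pyruvate dehydrogenase: 3 NADH);
# HMG-CoA reductase consumes 2 NADPH; mevalonate/phosphomevalonate kinases
# and the decarboxylase consume 3 ATP.
_PER_IPP = {
    "MEP": {
        "skeleton_glucose": 1.0,
        "reduction_steps": 3.0,
        "pathway_atp": 1.0,
        "ctp": 1.0,
        "glycolysis_atp_invested": 2.0,
        "glycolysis_atp_returned": 2.0,
        "nadh": 1.0,
    },
    "MVA": {
        "skeleton_glucose": 1.5,
        "reduction_steps": 2.0,
        "pathway_atp": 3.0,
        "ctp": 0.0,
        "glycolysis_atp_invested": 3.0,
        "glycolysis_atp_returned": 6.0,
        "nadh": 6.0,
    },
}


def glucose_cost(
    compound_class: str = "monoterpene",
    pathway: str = "MEP",
    conventions: EnergyConventions | None = None,
    skeleton_only: bool = False,
) -> CostLedger:
    """Build the itemized glucose-cost ledger for one terpene class.

    ``skeleton_only=True`` zeroes every energy line, leaving the pure
    carbon-skeleton bound (2 x 180.156 / 136.234 = 2.645 g/g for a
    monoterpene); it is a lower bound on the cost under any positive
    conventions.
    """
    if compound_class not in MOLAR_MASS:
        raise ValueError(f"unknown compound class {compound_class!r}")
    if pathway not in _PER_IPP:
        raise ValueError(f"unknown pathway {pathway!r}")
    conv = conventions or EnergyConventions()
    n = IPP_PER_MOLECULE[compound_class]
    s = _PER_IPP[pathway]
    if skeleton_only:
        return CostLedger(
            compound_class=compound_class, pathway=pathway, n_ipp=n,
            skeleton_glucose=n * s["skeleton_glucose"],
            atp_demand=0.0, ctp_demand=0.0, nadph_demand=0.0,
            atp_credit=0.0, nadh_credit=0.0, conventions=conv,
        )
    return CostLedger(
        compound_class=compound_class,
        pathway=pathway,
        n_ipp=n,
        skeleton_glucose=n * s["skeleton_glucose"],
        atp_demand=n * (s["pathway_atp"] + s["glycolysis_atp_invested"]),
        ctp_demand=n * s["ctp"],
        nadph_demand=n * s["reduction_steps"] * conv.reductant_per_2e_step,
        atp_credit=n * s["glycolysis_atp_returned"],
        nadh_credit=n * s["nadh"],
        conventions=conv,
    )


class InsufficientDataError(ValueError):
    """No usable girdled-only trees to estimate the maintenance fraction."""


def maintenance_fraction(
    girdled_noninoculated: Cohort | list[TreeRecord],
    pool: str = "total_nsc",
) -> float:
    """Mean percent NSC drawdown of girdled, noninoculated trees.

    This is the fraction of the pre-inoculation pool assumed to be committed
    to baseline maintenance metabolism (and hence unavailable for defense
    synthesis).  ``pool`` selects total NSC (default) or soluble sugars only.
    Trees with a zero pre pool are excluded with a warning.
    """
    if pool not in ("total_nsc", "total_sugar"):
        raise ValueError(f"unknown NSC pool {pool!r}")
    vals = []
    for t in girdled_noninoculated:
        if not (t.girdled and not t.inoculated and t.nsc_post is not None):
            continue
        pre = getattr(t.nsc_pre, pool)
        post = getattr(t.nsc_post, pool)
        if pre <= 0:
            warnings.warn(f"{t.tree_id}: zero pre-inoculation NSC, excluded")
            continue
        vals.append(100.0 * (pre - post) / pre)
    if not vals:
        raise InsufficientDataError(
            "no girdled noninoculated trees with usable pre/post NSC"
        )
    return float(np.mean(vals))


def nsc_available(nsc_pre: float, maintenance: float) -> float:
    """NSC remaining for defense after maintenance (% DW).

    nsc_available = nsc_pre * (100 - maintenance) / 100.
    """
    if nsc_pre < 0:
        raise ValueError("nsc_pre must be >= 0")
    if not (0.0 <= maintenance <= 100.0):
        raise ValueError(f"maintenance fraction {maintenance} outside [0, 100]")
    return nsc_pre * (100.0 - maintenance) / 100.0


def max_potential_mst(nsc_avail: float, cost: float) -> float:
    """Largest terpene increment the available NSC could fund (mg g^-1).

    ``nsc_avail`` is % DW (converted to mg g^-1); ``cost`` is g glucose per
    g terpene.
    """
    if cost <= 0:
        raise ValueError("glucose cost must be > 0")
    if nsc_avail < 0:
        raise ValueError("nsc_available must be >= 0")
    return pct_dw_to_mg_per_g(nsc_avail) / cost


def potential_percent_induction(
    max_potential: float, observed_delta_t: float
) -> float | None:
    """Maximum de novo contribution as % of the observed induction.

    Returns ``None`` (excluded: no induction) when the observed change is
    not positive — a tree that did not induce has no induction to budget.
    """
    if max_potential < 0:
        raise ValueError("max_potential must be >= 0")
    if observed_delta_t <= 0:
        return None
    return 100.0 * max_potential / observed_delta_t


@dataclass(frozen=True)
class DeNovoBudget:
    """Full de novo synthesis budget for one inoculated+girdled tree."""

    tree_id: str
    nsc_pre: float                  # % DW (chosen pool)
    maintenance: float              # %
    nsc_avail: float                # % DW
    glucose_cost: float             # g glucose per g MST
    max_potential_mst: float        # mg g^-1
    observed_delta_t: float         # mg g^-1 (girdle-corrected)
    potential_percent: float | None  # % of observed induction, None if excluded

    @property
    def excluded(self) -> bool:
        """True when the tree showed no induction (post <= pre)."""
        return self.potential_percent is None


def budget_for_tree(
    tree: TreeRecord,
    cost: float,
    maintenance: float,
    delta_t_corrected: float,
    pool: str = "total_nsc",
    allow_non_ig: bool = False,
) -> DeNovoBudget:
    """Chain the budget for one tree: available NSC -> max potential ->
    percent of observed induction.

    Defined only for inoculated+girdled trees (local NSC is the sole
    substrate there); ``allow_non_ig=True`` overrides for exploratory use.
    """
    if not (tree.girdled and tree.inoculated) and not allow_non_ig:
        raise ScopeError(
            f"{tree.tree_id}: de novo budget is defined for inoculated+girdled "
            f"trees only (treatment {tree.treatment}); pass allow_non_ig=True "
            f"to override"
        )
    pre = getattr(tree.nsc_pre, pool)
    avail = nsc_available(pre, maintenance)
    max_pot = max_potential_mst(avail, cost)
    return DeNovoBudget(
        tree_id=tree.tree_id,
        nsc_pre=pre,
        maintenance=maintenance,
        nsc_avail=avail,
        glucose_cost=cost,
        max_potential_mst=max_pot,
        observed_delta_t=delta_t_corrected,
        potential_percent=potential_percent_induction(max_pot, delta_t_corrected),
    )
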