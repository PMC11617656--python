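# Methods

This note records the models implemented in `terpenebudget`, the defaults
and their rationale, what the synthetic cohort does and does not emulate,
and the numerical choices a maintainer would want to know.

## Study structure

The experimental unit is a single *Pinus edulis* tree carrying: a watering
group (watered vs drought) and a drought stratum defined by predawn shoot
water potential ψ_pd (well-watered −0.31…−0.91 MPa, mild −1.66…−2.85,
moderate −2.86…−3.61); girdle and fungal-inoculation flags forming four
treatment cells (C, G, I, I+G) balanced within stratum; pre- and
post-inoculation mono+sesquiterpene (MST) concentrations (mg g⁻¹ DW, total
and a 43-compound matrix); pre/post NSC pools (starch, sucrose, glucose,
fructose, % DW); inner-bark osmolality (mmol kg⁻¹) and osmometer chamber
temperature (K). Units are fixed package-wide and the single unit
conversion, 1 % DW = 10 mg g⁻¹, lives in one function.

## Girdle resin-loss correction

Girdling bleeds stored resin, deflating the post-treatment terpene pool of
girdled trees independently of any biosynthetic response. Girdled-only
trees measure this artifact directly: their relative MST change
(T_post − T_pre)/T_pre is regressed by OLS on drought-stress magnitude
−ψ_pd. The fitted line (slope expressed per MPa of stress; a positive slope
means droughted trees lose less resin, consistent with lower resin
pressure) predicts a per-tree correction for inoculated+girdled trees,
clipped to [−1, 0]: a relative loss below −1 is physically impossible and a
predicted gain is treated as "no loss".

Two application conventions are implemented:

- `printed` (default): ΔT_corrected = ΔT_raw (1 + Correction);
- `add_back_absolute`: ΔT_corrected = ΔT_raw − Correction × T_pre.

The two disagree in sign behaviour for positive raw inductions (the first
shrinks a positive ΔT_raw, the second always adds the estimated absolute
loss back). Neither exactly inverts a multiplicative loss applied to the
post pool; the default follows the multiplicative form, the alternative is
one flag away, and every output labels the convention used. Downstream
conclusions should be (and in the test suite are) insensitive to the choice
at the qualitative level.

OLS, not robust regression, is used deliberately: the correction is a small
linear adjustment fitted to ≤ a dozen trees and robust variants would hide
rather than reveal influential points (diagnostics — n, R², residual sd,
coefficient SEs — are always reported).

## Stoichiometric glucose cost

The cost ledger prices terpene synthesis from glucose through the plastidic
MEP route. Per C5 isoprenoid unit (IPP/DMAPP):

| item | mol per C5 unit |
|---|---|
| glucose, carbon skeleton (→ pyruvate + GA3P, one CO₂ lost at DXS) | 1 |
| two-electron reduction steps (DXR, IspG, IspH) | 3 |
| kinase ATP (IspE) | 1 |
| CTP activation (IspD) | 1 |
| glycolytic ATP invested / returned | 2 / 2 |
| glycolytic NADH credit | 1 |

Net ATP (including CTP at 2 ATP equivalents and NADH credited at P/O 2.5)
and NADPH (12 mol per mol glucose via oxidative pentose phosphate; ATP 32
mol per mol glucose respired) are converted to glucose equivalents and
added to the skeleton. For a C10H16 monoterpene (two C5 units, M = 136.234
g mol⁻¹) this gives 2.53125 mol glucose per mol, i.e. **3.347 g glucose per
g terpene**; a C15H24 sesquiterpene costs the same per gram because both
classes are (C5H8)ₙ. The carbon-skeleton-only bound, 2 × 180.156/136.234 =
2.645 g g⁻¹, is available via `skeleton_only=True` and is a lower bound on
the cost under physiologically plausible conventions. A cytosolic MVA
ledger (1.5 glucose per C5 via three acetyl-CoA, 2 NADPH at HMG-CoA
reductase, 3 kinase/decarboxylase ATP, 6 NADH credits) is implemented but
off by default, since a single blended cost is applied to total MST.

The respiratory conventions are explicit configuration, not constants
buried in code: changing any of them propagates transparently through the
ledger, and the full itemized account (never just the scalar) is reported.
The main-text cost (3.34) and a figure-caption variant (3.54) disagree in
the source literature; this package targets 3.34 and does not average.

## De novo budget

For each inoculated+girdled tree — girdling guarantees only *local* NSC
could have fuelled synthesis —

- NSC_available = NSC_pre × (100 − %maintenance)/100, with %maintenance the
  mean relative NSC drawdown of girdled-only trees (cohort-level mean, not
  per-tree, because the girdled-only cells estimate a population baseline);
- max potential MST = 10 × NSC_available / cost (mg g⁻¹);
- potential percent induction = 100 × max potential / ΔT_corrected, defined
  only when ΔT_corrected > 0; non-inducing trees carry an explicit
  "excluded" marker.

The maintenance pool defaults to total NSC with a soluble-sugars-only
option (the source does not state which pool was used; soluble sugars are
~98% of the inner-bark pool, so the two differ little). Setting maintenance
to 0 is the documented sensitivity mode (all pre-inoculation NSC assumed
available), which weakly increases every potential percentage.

## Water relations

ψ_solute = −osmolality × 8.3144598×10⁻⁶ × T (MPa, van 't Hoff with the gas
constant collected into the unit conversion), and estimated turgor
ψ_pressure = ψ_pd − ψ_solute. Shoot predawn ψ is used as the inner-bark
water potential with no gradient correction — an approximation inherited
from the measurement design; "estimated" is part of the quantity's name for
that reason. Default chamber temperature is 305.0 K when unmeasured.

## Statistical layer

Linear models are statsmodels OLS with **type-II** sums of squares;
residual normality is reported (Shapiro–Wilk) but never used to switch
methods automatically. Tukey-HSD uses the studentized-range distribution.
The drought factor is binary (watered vs mild+moderate combined) in all
models. Bray–Curtis dissimilarities (scipy) operate on row-normalised
compositions by default.

The multi-factor PERMANOVA is implemented in this package: with
A = −½D², G = JAJ (Gower centering), the sums of squares of nested design
matrices X₀ ⊂ … ⊂ X_full are tr(H_k G) differences (sequential partition,
matching vegan's `adonis2(..., by="terms")`), pseudo-F per term is
(SS_term/df_term)/(SS_res/df_res), and p = (1 + #{F_perm ≥ F_obs})/(n_perm+1)
under permutation of **raw sample labels** (whether the source permuted raw
labels or reduced-model residuals is unstated; raw-label permutation is the
documented choice here). Default n_perm = 999 with the seed recorded in
every report. When the residual scatter is numerically zero (perfect
separation) the pseudo-F is ∞ and only permutations reproducing the
partition tie with it. scikit-bio's one-way PERMANOVA and vegan's adonis2
serve as independent cross-checks in the test suite, never as the
implementation. NMDS is deliberately replaced by PCoA (scikit-bio) for
visualisation: deterministic, no stress-convergence ambiguity; all
compositional inference runs through PERMANOVA either way.

## Synthetic cohort generator

The generator's defaults are the study conditions: 14/16/16 trees per
stratum with ψ_pd uniform in the stratum ranges (ranges are reported
quantities; uniform is the least-committal distribution consistent with
them); treatments cycled through a shuffled order within stratum (cells of
3–4); induced increment linear in ψ_pd with slope 15.9 mg g⁻¹ MPa⁻¹
anchored to 49.3 mg g⁻¹ at the watered-stratum mean ψ; girdle loss linear
between anchors (−0.31 MPa, −0.43) and (−3.61 MPa, 0), truncated to [−1, 0];
NSC depletion by treatment 0/52/76/89% (sd 8/11/10/10); soluble sugars
5.4 ± 1.4% DW with starch 0.3% (watered) vs 0.03% (drought); chamber
temperature 305.0 ± 0.2 K; four trees with missing post-inoculation tissue,
drawn from the driest stratum.

Choices the source does not pin down, fixed once here: constitutive MST
30 ± 8 mg g⁻¹ (placeholder scale, never used as ground truth); additive
Gaussian induction noise (sd 10 mg g⁻¹) censored so MST_post ≥ 0 for
nongirdled trees; purely *relative* noise (sd 0.05) for girdled trees, so a
girdled-only tree's relative MST change is exactly loss(ψ) + η — this keeps
the loss-line regression homoskedastic and correctly specified, which is
what makes parameter-recovery tests meaningful; osmolality
800 + 100·(−ψ_pd) ± 60 mmol kg⁻¹, an osmotic-adjustment regime placing most
watered trees above zero estimated turgor and most moderate-drought trees
below; compositions Dirichlet (concentration 150) around a constitutive
mean vector, tilted along a fixed ±1 log-pattern for watered inoculated
trees only (drought overrides the induced compositional shift).

What the generator does **not** emulate: resin-duct pressure dynamics,
phloem transport, temporal NSC kinetics, compound-level biology (the 43
compound means are arbitrary but seed-fixed), or measurement error
structure beyond the Gaussian/relative noise above. Passing recovery tests
therefore demonstrate that the estimators are correct and calibrated under
the stated statistical structure — not that the structure is true of real
trees.

## Problem sizes and determinism

Parameter-recovery checks scale the cohort to 500 trees
(largest-remainder rounding of the 14:16:16 strata) over 100 seeded
replicates; the permutation-test calibration uses 200 simulations at 199
permutations on the 46-tree cohort. These sizes keep every estimator in
its well-behaved regime while each suite runs in seconds to minutes.
Replicate seeds derive from a fixed master `SeedSequence`; every stochastic
stage of the pipeline takes an explicit seed, and identical configuration
plus seeds reproduce byte-identical CSV/JSON outputs (fixed float
formatting, sorted JSON keys, checksums in a manifest).

Note on the ±2 SE recovery criterion: a ±2·SE interval covers a true
parameter with probability ≈ 95.4% under exact specification, so demanding
coverage in ≥95 of 100 replicates leaves a margin of a fraction of one
replicate; the recovery test documents this and fixes its seed stream
rather than tuning it.

## Known limitations

- The printed correction convention shrinks positive inductions rather than
  restoring the pre-loss value; the add-back convention over-corrects
  multiplicative losses. Both are reported; neither is claimed as "truth".
- The de novo budget is an upper bound by construction (all remaining NSC
  assumed convertible); diterpenes are not costed, which would only lower
  the de novo share.
- Estimated ψ_pressure inherits the shoot-ψ ≈ bark-ψ assumption.
- The maintenance fraction is a cohort mean; per-tree maintenance is not
  identifiable from the design.
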