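# terpenebudget

Can a drought-stressed pinyon pine (*Pinus edulis*) pay for its induced
chemical defense? When a bark-beetle-vectored fungus attacks, the tree
accumulates mono- and sesquiterpenes (MST) in the inner bark. That induced
response could come from *de novo* synthesis fuelled by local nonstructural
carbohydrates (NSC), or from preformed resin mobilised from storage — and
drought could constrain either route. This package implements, as a tested
analysis pipeline over tree-level data, the accounting needed to separate
those hypotheses:

1. **Girdle resin-loss correction.** Girdling (severing phloem to isolate
   the local NSC pool) bleeds resin from the wound. The relative MST loss of
   girdled-only trees, `(T_post − T_pre)/T_pre`, is regressed on predawn
   water potential ψ_pd (watered trees lose more), and the fitted line
   predicts a per-tree `Correction ∈ [−1, 0]` for inoculated+girdled trees:
   `ΔT_corrected = ΔT_raw + ΔT_raw × Correction` (an additive
   "add back the absolute loss" convention is available behind a flag).
2. **Stoichiometric cost of synthesis.** An itemized ledger prices one mole
   of terpene built from glucose via the plastidic MEP pathway: one glucose
   per C5 isoprenoid unit for the carbon skeleton, plus 3 NADPH, 1 ATP and
   1 CTP per unit, minus glycolytic co-product credits, converted to glucose
   equivalents (ATP 32 mol/mol glucose, NADPH 12 mol/mol via oxidative
   pentose phosphate, NADH credited at P/O 2.5, CTP = 2 ATP). The defaults
   give **3.35 g glucose per g MST**, identical for C10H16 and C15H24.
3. **De novo budget.** `NSC_available = NSC_pre × (100 − %NSC_maintenance)/100`,
   with the maintenance percentage estimated as the mean NSC drawdown of
   girdled-only trees; the maximum potential MST increment is
   `10 × NSC_available / cost` (mg g⁻¹), and its ratio to the observed
   induction gives the maximum percent of the response attributable to
   *de novo* synthesis. Trees that did not induce are excluded, not divided by.
4. **Water relations.** Inner-bark solute potential from osmometry,
   `ψ_solute = −mOsm·kg⁻¹ × 8.3144598×10⁻⁶ × K` (MPa), and estimated turgor
   `ψ_pressure = ψ_pd − ψ_solute`.
5. **Statistics.** OLS with type-II ANOVA and Tukey-HSD (statsmodels),
   Bray–Curtis dissimilarity, a multi-factor PERMANOVA with raw-label
   permutation (implemented here; cross-checked against scikit-bio and
   vegan), and PCoA for visualisation.

Because the study's tree-level dataset is external, a first-class
**synthetic cohort generator** reproduces the experiment's structure — 46
trees in three ψ_pd strata, four treatments balanced within stratum,
induction declining 15.9 mg g⁻¹ per MPa, drought-dependent girdle loss,
treatment-specific NSC depletion (52/76/89%), osmotic adjustment, and a
43-compound composition that shifts only in watered inoculated trees — so
every stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
cohort (seed 0) and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_girdle_correction.py
python analysis/03_water_relations.py
python analysis/04_stoichiometric_budget.py
python analysis/05_statistics.py
```

which prints, among other lines:

```
cohort: 46 trees (14 watered, 32 drought), 4 missing post-inoculation tissue
girdle-loss line (n=11 girdled-only trees): loss = -0.483 + 0.138 * (-psi_pd), R^2 = 0.92
corrections for I+G trees span -0.43 .. -0.02
glucose cost: 3.347 g glucose per g MST (2.5312 mol glucose per mol)
maintenance fraction (girdled-only mean NSC drawdown): 50.9%
psi_pd x inoculation interaction: p = 0.0012
induction ~ psi_pd slope (I cell): 15.9 +/- 3.6 mg g^-1 MPa^-1
induction ~ pre-inoculation NSC: p = 0.24 (R^2 = 0.07)
induction ~ psi_pressure: R^2 = 0.32, p = 0.0072
induction ratio, positive vs lost turgor: 11.1x
```

Read: the fungal induction shrinks steeply with drought stress (the slope
recovers the configured 15.9 mg g⁻¹ MPa⁻¹), pre-attack carbohydrate pools do
*not* predict induction, but estimated inner-bark turgor does — the
generator reproduces the qualitative contrast between a substrate-limited
and a turgor-limited defense. The same stages are available as a CLI
(`terpene-budget simulate|correct|water|budget|stats|run`) and as one call:

```python
from terpenebudget import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=7))
print(report.headline["glucose_cost_g_per_g"])   # 3.347...
```

Identical config and seed reproduce byte-identical outputs.

## Layout

- `src/terpenebudget/` — library: `datamodel`, `simulate`, `girdle`,
  `stoichiometry`, `water`, `stats`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers (above).
- `tests/` — unit, property and acceptance-level tests.
- `docs/methods.md` — the model, parameter defaults, generator assumptions
  and known limitations.
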