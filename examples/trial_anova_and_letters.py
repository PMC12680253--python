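"""Trial ANOVA with interaction-model selection and Tukey letters.

Fits yield on a synthetic multi-environment trial: the hybrid x
condition interaction is kept only if its F test is significant, field
row/column covariates only if screened in, and condition means get a
compact letter display (conditions sharing a letter do not differ at
P < 0.05).
"""

from maizedig import simulate, stats, traits
from maizedig.pipeline import table1_report

wide = traits.long_to_wide(simulate.gen_trial(simulate.TrialDesign(seed=11)))
wide = traits.derive_trial_traits(wide)

res = stats.fit_trait_anova(wide, "yield")
print(f"chosen model: {res.model} (interaction p = {res.interaction_p:.3g}; "
      f"row covariate: {res.include_row}, column covariate: {res.include_col})")
print(res.table.round(3))

print("\nCondition means with Tukey letters:")
t1 = table1_report(wide, ["yield", "digestible_yield", "cw_digestibility"])
for trait, grp in t1.groupby("trait"):
    row = "  ".join(f"{r.condition}={r.mean:.2f}{r.letters}" for r in grp.itertuples())
    print(f"  {trait:18s} {row}")
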