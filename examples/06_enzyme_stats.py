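"""Mitotype and sex effects on mitochondrial enzyme activities.

Simulates per-individual ETS, COX and CS activities across the four
sex x mitotype cells (defaults: 31%/33% mitotype reductions for ETS/COX,
42% sex reduction for CS) and runs the nonparametric suite:
percent-reduction bootstrap, Kruskal-Wallis, Holm-adjusted Wilcoxon
post hocs, and the mtDNA copy-number fold.
"""
from mitoduo import (SynthConfig, copy_number_fold, effect_summary,
                     factorial_tests, simulate_phenotypes)

table = simulate_phenotypes(SynthConfig(seed=7))
print(f"{len(table)} individuals "
      f"({dict(table.groupby(['sex', 'mitotype']).size())})\n")

print(effect_summary(table, seed=7).to_string(index=False))
print()
for endpoint in ("ETS", "COX", "CS"):
    rep = factorial_tests(table, endpoint)
    print(f"{endpoint}: Kruskal-Wallis H={rep.kw_statistic:.1f} p={rep.kw_p:.2e}; "
          f"mitotype p={rep.marginal['mitotype'][1]:.2e}, "
          f"sex p={rep.marginal['sex'][1]:.2e}")

m = table.loc[table.mitotype == "M", "cytb_copy"]
f = table.loc[table.mitotype == "F", "cytb_copy"]
fold = copy_number_fold(m, f, seed=7)
print(f"\nmtDNA copy-number fold (M/F): {fold.fold:.2f} "
      f"[{fold.ci_low:.2f}, {fold.ci_high:.2f}] 95% CI")
# ETS and COX respond to the mitotype regardless of sex; CS responds to
# sex regardless of mitotype; M-carriers run ~3x the mtDNA copy number,
# inside the 2-5x band.
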