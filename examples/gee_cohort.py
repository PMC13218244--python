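"""Clustered group comparison with generalized estimating equations.

Simulates a two-eyes-per-subject cohort with a planted -3 unit group
effect and within-subject correlation 0.6, then fits a linear GEE with
an exchangeable working correlation and robust sandwich errors.
"""

from oculovasc.stats import bh_fdr, gee_fit
from oculovasc.synth import CohortParams, gen_cohort

params = CohortParams(n_ctrl=100, n_msnon=100, n_mson=0, rho=0.6, seed=11,
                      outcome_means={"Y": 50}, outcome_sds={"Y": 5},
                      effect_sizes={"Y": {"MSnON": -3.0}})
df, truth = gen_cohort(params)

fit = gee_fit(df, "Y", ["group"], reference={"group": "Ctrl"})
term = "group[MSnON]"
print(f"planted effect: {truth['betas']['Y'][term]:.1f};  "
      f"estimated beta = {fit.params[term]:.3f} "
      f"(95% CI {fit.ci_lo[term]:.3f} to {fit.ci_hi[term]:.3f})")
print(f"estimated within-subject correlation rho = {fit.rho_hat:.3f} (truth 0.6)")
print(f"robust p = {fit.pvalues[term]:.2e}; "
      f"BH-adjusted over a 5-test family = {bh_fdr([fit.pvalues[term]] + [0.2]*4)[0][0]:.2e}")
print("The sandwich variance stays valid even if the working correlation is")
print("misspecified; eyes of one subject never count as independent.")
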