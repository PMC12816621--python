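"""3-year survival and clinical associations across glycolytic tertiles.

Simulates a 300-sample bulk cohort in which the high-glycolysis tertile
carries 3x the event hazard of the low tertile, then computes the 3-year
Kaplan-Meier endpoint (log-rank + trend) and tests each categorical
covariate for association with the glycolytic group.
"""

import glycostrat as g

co = g.gen_cohort(g.CohortSimConfig(n_samples=300, hazard_ratio_high_vs_low=3.0, seed=7))
print("group sizes:", co.df["group"].value_counts().to_dict())

fit = g.km_fit(co, horizon=36.0)
print(f"log-rank p = {fit.logrank_p:.3g}, trend p = {fit.trend_p:.3g}")
for grp, sub in fit.curves.groupby("group", observed=True):
    print(f"  {grp}: S(36 mo) = {sub['survival'].iloc[-1]:.2f}")

results = [g.association_test(g.contingency(co, v), v) for v in co.covariate_names()]
for r in g.rank_associations(results):
    flag = "*" if r.significant else " "
    print(f"  {r.rank}. {r.variable:<12} p = {r.p_primary:.4f} ({r.test_used}){flag}")

# Survival drops fastest in the High tertile (significant log-rank and
# monotone trend); the covariates were simulated independently of the
# score, so their association p values are non-significant, as expected.
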