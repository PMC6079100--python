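"""Cohort signature activities: KS scores, correlation, survival split.

Simulates a 400-patient cohort with anti-correlated latent TRPS1/YAP
activities (r = -0.85) in which high TRPS1-axis activity worsens
survival (hazard ratio 2 per SD), recovers per-patient activities with
the signed per-sample KS score, and compares survival above/below the
third quartile of recovered TRPS1 activity.
"""

from sortscreen import signatures, simulate

cohort, truth = simulate.simulate_cohort(
    n_patients=400, latent_correlation=-0.85, hazard_ratio_per_sd=2.0,
    censor_rate=0.2, seed=11,
)
activities = signatures.activity_scores(
    cohort.expression, cohort.trps1_repressed_set, cohort.yap_induced_set
)
rho, rho_p = signatures.spearman_rho(
    activities["trps1_activity"], activities["yap_activity"]
)
print(f"recovered TRPS1 vs YAP activity: Spearman rho = {rho:.2f} "
      f"(p = {rho_p:.2e}); planted latent correlation was -0.85")

strata = signatures.quartile_stratify(activities["trps1_activity"])
comparison = signatures.km_logrank(
    cohort.clinical["time"], cohort.clinical["event"], strata
)
print(f"Q3 stratification: {comparison.group_sizes}")
print(f"log-rank chi-square = {comparison.chi_square:.1f}, "
      f"p = {comparison.p_value:.2e}")
# A large chi-square means the top-quartile activity group has clearly
# separated survival, recovering the planted hazard effect.
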