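"""Survival stratified by 9p21 status: Kaplan-Meier, log-rank, Cox.

Simulates a cohort where 9p21 loss doubles the death hazard, then recovers
that hazard ratio and compares the stratified curves.
"""

from ninep21.simulate import SimulationConfig, generate_cohort
from ninep21.survival import cox_fit, km_estimate, logrank_test

cohort = generate_cohort(SimulationConfig(n_samples=800, seed=5, hr_loss=2.0))
clin = cohort.clinical.data
truth = cohort.ground_truth

groups = truth["genotype"]
res = logrank_test(clin["os_time"], clin["os_event"], groups[groups.isin(["WT", "LOSS"])])
print(f"log-rank chi2 = {res.statistic:.2f}, p = {res.p:.3g}")

for g in ("WT", "LOSS"):
    ids = truth.index[truth["genotype"] == g]
    curve = km_estimate(clin.loc[ids, "os_time"], clin.loc[ids, "os_event"])
    print(f"{g}: median OS = {curve.median:.1f} months")
# the LOSS group's median survival is roughly half the WT group's, as
# expected under a proportional-hazards ratio of 2.

cov = (groups == "LOSS").astype(float).rename("loss").to_frame()
fit = cox_fit(clin["os_time"], clin["os_event"], cov)
print(fit.round(3))
# hr should sit near the configured 2.0 with a CI excluding 1.
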